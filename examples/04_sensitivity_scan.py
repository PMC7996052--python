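"""One-at-a-time sensitivity of P uptake to soil and root parameters.

Runs a reduced scan (three levels, two replicates) over four parameters
and prints the percent-of-baseline responses.  Lateral-root length and
root-hair length move uptake far more than root-hair density -- the
model's headline sensitivity ranking.
"""

from oryzaroot import asymmetry_index, default_dj123_params, run_scan

params = default_dj123_params()
table = run_scan(params,
                 parameters=["soil_p", "ltype_length", "hair_length",
                             "hair_density"],
                 levels=(0.25, 1.0, 4.0), replicates=2, seed=7, n_nodes=20)

summary = table.groupby(["parameter", "level"])["percent"].mean()
print("P content as % of baseline:")
print(summary.round(1).to_string())

down, up = asymmetry_index(table, "soil_p")
print(f"\nsoil P asymmetry: -{down:.0f}% at 0.25x vs +{up:.0f}% at 4x "
      "(increases act more strongly than equal-ratio decreases)")
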