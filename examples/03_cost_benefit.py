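"""Phosphorus cost-benefit analysis by root class.

Costs are tissue weight x 0.8 ug P per mg; benefits are the simulated P
uptake.  Root hairs and S-type laterals recover their construction cost
within a day, the thick nodal roots take far longer -- the central
trade-off of a P-starved root system.
"""

from oryzaroot import (build_ledger, default_dj123_params, grow,
                       recovery_case1, recovery_case2, recovery_case3,
                       system_uptake)

params = default_dj123_params()
system = grow(params, seed=1, horizon=31)
res = system_uptake(system, at=31)

ledger = build_ledger(system, res, 31)
print(ledger.round(2).to_string())

daily = res.daily_uptake_ug(31)
nodal_daily = sum(daily[c] for c in ("primary", "nodal_branched",
                                     "nodal_fast", "nodal_tiller"))
print("\npay-off times (days):")
print(f"{'row':8s} {'case1':>7s} {'case2':>7s} {'case3':>7s}")
for row, cls, d in (("stype", "stype", daily["stype"]),
                    ("ltype", "ltype", daily["ltype"]),
                    ("nodal", "nodal_branched", nodal_daily)):
    c1 = recovery_case1(ledger.loc[row, "cost_ug"], d)
    c2 = recovery_case2(cls, params)
    c3 = recovery_case3(cls, params)
    fmt = lambda x: "never" if x == float("inf") else f"{x:.1f}"
    print(f"{row:8s} {fmt(c1):>7s} {fmt(c2):>7s} {fmt(c3):>7s}")

# case 1: cost / static daily uptake at 28 DAE
# case 2: growing single-class system with its hairs
# case 3: the same system without root hairs
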