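"""Apply the core-exclusion rules and the control-core check.

Shows the post-analytical boundary behaviour (counts below 50 or above
15,000, scores of exactly 100 %) and a TMA-level control check with a
failing negative control, as would happen with a staining problem.
"""

from ki67tma import CoreResult, check_controls, post_analytical_qc

for core in (
    CoreResult("c_49", 10, 39),      # 49 nuclei -> too few
    CoreResult("c_50", 10, 40),      # 50 nuclei -> passes
    CoreResult("c_100pct", 800, 0),  # exactly 100 % -> staining problem
    CoreResult("c_ok", 180, 420),    # unremarkable core
):
    d = post_analytical_qc(core)
    print(f"{core.core_id:9s} total={core.total_nuclei:5d} -> {d.status:8s} {d.reasons}")

controls = [
    CoreResult("pos", 190, 10, is_control=True, control_kind="positive"),   # 95 %
    CoreResult("neg", 60, 140, is_control=True, control_kind="negative"),   # 30 % !
    CoreResult("blank", 0, 3, is_control=True, control_kind="blank"),
]
report = check_controls(controls, tma_id="tma_01")
print(f"\nTMA control check passed={report.passed}; failures={report.failures}")
print("a hot negative control signals diffuse DAB background on the whole TMA")
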