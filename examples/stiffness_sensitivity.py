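"""Check that study conclusions survive +/-43 % ligament stiffness error.

Reported soft-tissue stiffnesses vary widely between specimens; this
script rescales every band uniformly to 0.57x and 1.43x and verifies the
key disease/correction comparisons keep their direction.
"""

from footmech.analysis import default_suite, run_suite
from footmech.mechanics import SolverOptions

solver = SolverOptions(trust_radius_mm=12.0, n_ramp_stages=4)
for scale in (0.57, 1.0, 1.43):
    table, _ = run_suite(
        default_suite(seed=0, solver=solver, stiffness_scale=scale,
                      names=("normal", "flatfoot", "MCO", "Evans"))
    )
    rep = table.reports
    d_t1 = rep["flatfoot"].angles.l_t1mt - rep["normal"].angles.l_t1mt
    d_hf = rep["MCO"].angles.hindfoot - rep["flatfoot"].angles.hindfoot
    d_cc = rep["Evans"].calcaneocuboid_force_N - rep["flatfoot"].calcaneocuboid_force_N
    print(
        f"stiffness x{scale:4.2f}:  flatfoot dL-T1MT = {d_t1:+6.3f} deg,"
        f"  MCO d-hindfoot = {d_hf:+5.2f} deg,"
        f"  Evans d-CC force = {d_cc:+6.0f} N"
    )
print("\nSame signs across all three rows = the comparisons are robust.")
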