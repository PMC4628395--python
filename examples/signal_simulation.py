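"""Predict the 2-point bSSFP contrast from tissue relaxation and MT.

Evaluates the steady-state signal of healthy remote myocardium, an
edema-like lesion and blood at the 5/45-degree flip-angle pair, and the
resulting normalized signal change dS/S0.  Also writes a tidy sweep table
(signal vs flip angle, T1, T2, bound fraction) for plotting.
"""

from bssfp2pt import AcquisitionParams, delta_s_predicted, signal_sweep
from bssfp2pt.phantom import default_tissues

acq45 = AcquisitionParams(tr=3.2, te=1.2, flip_angle=45.0, rf_duration=0.6)
acq5 = acq45.with_flip_angle(5.0)

print("Predicted dS/S0 = (S45 - S5)/S5 x 100 per tissue:")
for name, tissue in default_tissues().items():
    ds = delta_s_predicted(acq5, acq45, tissue)
    print(
        f"  {name:7s} T1={tissue.t1:6.0f} ms T2={tissue.t2:5.0f} ms "
        f"F={tissue.bound_fraction:.2f} -> dS/S0 = {ds:6.1f} %"
    )
print(
    "\nThe lesion (long T2, depleted bound pool) sits far above the 197 % "
    "enhancement threshold;\nremote myocardium (strong MT, short T2) sits "
    "far below it — that separation is the method's contrast."
)

df = signal_sweep(
    acq45,
    flip_angles_deg=[5, 15, 25, 35, 45, 60],
    t1s_ms=[950, 1200],
    t2s_ms=[46, 80, 130],
    bound_fractions=[0.0, 0.05, 0.12],
)
df.to_csv("signal_sweep.csv", index=False)
print(f"\nwrote signal_sweep.csv ({len(df)} rows: flip angle x T1 x T2 x F)")
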