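"""Extract the 10-index HRV battery from a synthetic 5-minute recording.

Builds a tachogram with a 0.1 Hz (LF) and a 0.25 Hz (HF) autonomic
oscillation plus beat noise, then prints the time-domain indices (SDNN,
RMSSD, SDSD in ms; pNN50 in %) and the frequency-domain indices (band powers
in ms², normalized units in % of LF+HF, and the LF/HF balance ratio).
"""

from hrvcdet import StageProfile, frequency_domain, simulate_rr, time_domain

profile = StageProfile(stage="demo", mean_rr=800, lf_amp=25, hf_amp=40, noise_sd=10, duration=300)
rr = simulate_rr(profile, seed=1)

td = time_domain(rr)
fd = frequency_domain(rr)

print(f"{len(rr)} beats over {rr.duration_s:.0f} s")
print(f"SDNN  {td.sdnn:7.2f} ms   (overall variability)")
print(f"RMSSD {td.rmssd:7.2f} ms   (short-term, vagally mediated)")
print(f"SDSD  {td.sdsd:7.2f} ms")
print(f"pNN50 {td.pnn50:7.2f} %")
print(f"LF    {fd.lf_power:7.1f} ms^2   LF n.u. {fd.lf_nu:5.2f} %")
print(f"HF    {fd.hf_power:7.1f} ms^2   HF n.u. {fd.hf_nu:5.2f} %")
print(f"LF/HF {fd.lf_hf:7.3f}        (sympathovagal balance)")
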