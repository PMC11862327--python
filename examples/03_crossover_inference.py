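"""Full crossover analysis of a simulated study with known effects.

Generates a 16-subject study in which the active condition lowers RMSSD by
4 ms (stimulation phase) and 5 ms (after the caloric load), runs baseline
correction, pairwise differences, the studentized bootstrap, BH adjustment,
Cohen's dz and JZS Bayes factors, and prints the side-averaged effects table.
"""

from hrvcross import BootstrapConfig, RrSimConfig, StudyDesign, analyze_study
from hrvcross.pipeline import summarize_rr_dataset
from hrvcross.simulate import generate_study_dataset

effects = {
    ("rmssd", "taVNS", "stimulation"): -4.0,
    ("rmssd", "taVNS", "caloric_load"): -5.0,
    ("hr", "*", "caloric_load"): 3.3,
}
dataset = generate_study_dataset(
    StudyDesign(n_subjects=16, effect_table=effects, seed=3),
    RrSimConfig(duration=600.0),
)
summary, _ = summarize_rr_dataset(dataset)
result = analyze_study(summary, BootstrapConfig(n_resamples=10_000, seed=3))

table = result["effects"]
both = table[table["side"] == "both"]
print(both[["index", "phase", "b", "ci_lo", "ci_hi", "p_boot", "p_adj",
            "dz", "bf10"]].round(3).to_string(index=False))
print()
for factor, res in result["manova"].items():
    print(f"MANOVA {factor:>12}: V = {res.pillai_v:.3f}, "
          f"F({res.df1:.0f}, {res.df2:.0f}) = {res.f_stat:.2f}, p = {res.p_value:.4f}")
# the rmssd rows show b near -4 (stimulation) and -5 (caloric load) with
# BF10 >> 1, and the MANOVA flags the stimulation factor. sdrr and hf also
# decline: an RMSSD-only target is injected by scaling all variability
# sources together (a vagal-withdrawal-like change), which drags the other
# HRV indices along. The hr rows sit near 0 because the caloric-load HR rise
# hits both conditions and cancels in the taVNS - sham contrast.
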