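"""Compare ATAC peak values between conditions within region classes.

Peak values gain a 1.2x multiplier inside implanted advances in the
treated condition. Replicates are depth-normalized and averaged, peaks
are paired by nearest centers, and each class is tested with the
Wilcoxon matched-pairs signed-rank test.
"""

from retime import SyntheticSpec, make_feature_tracks, make_rt_profiles
from retime.atac import (
    average_replicates,
    match_peaks,
    normalize_peak_values,
    regional_peak_comparison,
)

spec = SyntheticSpec()
_, truth = make_rt_profiles(spec)
tracks = make_feature_tracks(spec, truth)

at = tracks["atac_peaks"]
n = spec.atac_replicates
normed = normalize_peak_values(
    [at[("control", f"r{i + 1}")] for i in range(n)]
    + [at[("treated", f"r{i + 1}")] for i in range(n)]
)
pairs = match_peaks(average_replicates(normed[:n]), average_replicates(normed[n:]))

classes = {"ADV": truth.implant_set("ADV"), "Early": truth.early, "Late": truth.late}
for cls, res in regional_peak_comparison(pairs, classes).items():
    print(f"{cls:6s} n={res.n_pairs:4d}  W={res.statistic:10.1f}  "
          f"p={res.p_value:.2e}  median shift={res.median_shift:+.1f}")
# Only the ADV class shows a significant positive shift (the implanted
# accessibility gain); Early and Late behave as nulls.
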