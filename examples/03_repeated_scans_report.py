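"""Repeated noisy scans with repositioning, summarized as mean and 95% CI.

Simulates three repetitions of the contrast-enhanced protocol (Gaussian
noise, ~2 degree / ~2 mm repositioning jitter) and of the non-contrast
reference protocol, scores the calcium-preserving images, and reports per
ring the mean 3 mm-equivalent Agatston score with its 95% CI, significance
against the reference by the non-overlapping-CI rule, and the relative
volume difference from the physical 377 mm^3.
"""

import pandas as pd

from speccal import (
    ScanProtocol,
    ScoringConfig,
    build_phantom,
    default_phantom_spec,
    phantom_manifest,
    score_volume,
    summarize_scores,
    trueca_image,
)

REPS = 3
config = ScoringConfig(slice_thickness_mm=3.0, slice_increment_mm=1.5)


def scan_rows(spec, method, image_of, seed):
    protocol = ScanProtocol(fov_mm=27.5, matrix=64, seed=seed)  # default noise
    manifest = phantom_manifest(spec)
    ref_vol = {m["name"]: m["analytic_volume_mm3"] for m in manifest}
    rows = []
    for rep in range(REPS):
        volume = build_phantom(spec, protocol, repetition=rep)
        report = score_volume(
            image_of(volume), volume.spacing, config,
            manifest=manifest, origin=volume.origin,
        )
        for entry in report.entries:
            if entry.name == "unassigned":
                continue
            rows.append({
                "method": method, "thickness_mm": 3.0, "contrast": spec.lumen_contrast_fraction,
                "name": entry.name, "repetition": rep,
                "agatston_3mm": entry.agatston_3mm, "volume_mm3": entry.volume_mm3,
                "reference_volume_mm3": ref_vol[entry.name],
            })
    return rows


ccta = default_phantom_spec(contrast_fraction=1.0)
tnc = default_phantom_spec(contrast_fraction=0.0)
scores = pd.DataFrame(scan_rows(ccta, "trueca", trueca_image, seed=17))
reference = pd.DataFrame(
    scan_rows(tnc, "cac_ct", lambda v: v.conventional, seed=23)
)
reference["contrast"] = 1.0  # compare against the reference cell per ring

summary = summarize_scores(scores, reference)
columns = ["name", "mean", "ci_low", "ci_high", "significant_vs_reference"]
extra = [c for c in ("relative_volume_difference_pct", "absolute_volume_mm3") if c in summary]
print(summary[columns + extra].round(1).to_string(index=False))
print("\nsignificant_vs_reference uses the non-overlapping 95% CI rule;")
print("relative_volume_difference_pct compares the mean volume score to 377 mm^3.")
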