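# speccal

Calcium-preserving virtual-non-contrast (VNC) coronary calcium scoring on
contrast-enhanced spectral CT, with a synthetic dual-layer phantom simulator.

## The problem

Coronary artery calcium (CAC) is quantified with the Agatston score on a
dedicated non-contrast CT: per slice, 8-connected lesions of voxels >= 130 HU
with area >= 0.5 mm² contribute *area x weight*, where the weight is 1-4 by
the lesion's maximum HU (130/200/300/400 HU bins). Deriving the score from
the contrast-enhanced angiography scan instead would remove a scan from the
workflow — but iodine and calcium overlap in conventional HU, and standard
VNC reconstructions model voxels with a water/iodine basis, so part of the
calcium signal is attributed to iodine and suppressed with it: medium- and
low-density calcifications vanish.

Dual-layer spectral CT provides photoelectric-effect and Compton-scatter base
images in which the two materials separate. speccal implements a
calcium-preserving classification: voxel **r** is calcium when

```
HU_PE(r) <= HU_Compton(r) * slope + intercept        (calcium mask M(r) = 1)
I_out(r) = M(r) * I_conv(r)
```

i.e. a linear decision boundary in base-image space builds a binary calcium
mask that is multiplied into the conventional 120 kVp image — calcium voxels
keep their attenuation, everything else becomes 0 HU, and the result is
scored with the unmodified Agatston/volume machinery. The (slope, intercept)
pair is fitted by differential evolution minimizing the summed absolute
per-calcification Agatston error against non-contrast reference scans; the
shipped default is (3.69, -3361).

Intended users: medical-physics and image-analysis researchers studying CAC
scoring on spectral CT, who need a controlled, fully synthetic test bed
rather than scanner data.

## What is in the package

- `speccal.phantom` — synthetic spectral scans of a hollow-artery insert:
  five annular CaHA calcifications (75-800 mg/cc; 96-1044 HU; physical
  volume 377 mm³ each) in a blood-equivalent lumen at 0-150% clinical
  contrast dose, rasterized with sub-voxel partial volume, seeded
  repositioning jitter, per-channel Gaussian noise, and overlapping-slab
  slice reconstruction (e.g. 3.0/1.5 mm or 0.67/0.335 mm).
- `speccal.spectral` — the calcium mask / calcium-preserving image, plus a
  simplified iodine-suppressing VNC baseline that reproduces the
  classical failure mode.
- `speccal.scoring` — Agatston score (raw and 3 mm-equivalent), volume
  score, lesion finding, and the analytic ideal-score path.
- `speccal.optimize` — differential-evolution boundary fitting with the
  0.1%-improvement stopping rule.
- `speccal.report` — mean / 95% CI over repetitions, non-overlapping-CI
  significance, relative volume differences.

A thin CLI (`speccal generate|trueca|vnc|score|fit-boundary|report`) wraps
the same functions for shell use; `examples/` contains four narrative
scripts, one per capability.

## Worked example

`python examples/02_trueca_vs_vnc.py` scores one noiseless synthetic scan at
100% contrast dose (3.0/1.5 mm) three ways and prints:

```
      region | conventional |          vnc |       trueca
      75mgcc |          0.0 |          0.0 |         11.8
     100mgcc |          0.0 |          0.0 |         23.6
     200mgcc |          0.0 |          0.0 |        365.2
     400mgcc |       3355.1 |        179.1 |        576.8
     800mgcc |          0.0 |        483.0 |        783.2
calcium_free |          0.0 |          0.0 |          0.0
```

Reading the table (3 mm-equivalent Agatston points): on the raw conventional
image the iodine-filled lumen is itself above 130 HU, so the whole artery
merges into one meaningless lesion. The iodine-suppressing VNC baseline
detects only the 400 and 800 mg/cc rings — everything below 400 mg/cc is
pushed under the 130 HU threshold. The calcium-preserving image detects all
five densities (the 75 and 100 mg/cc rings through calcium/iodine
partial-volume voxels that exceed 130 HU while still classifying as calcium)
and keeps the calcium-free segment at exactly zero.

`python examples/03_repeated_scans_report.py` adds noise and repositioning
jitter over repeated scans and prints per-ring means with 95% CIs, the
non-overlapping-CI significance flag against a non-contrast reference, and
relative volume differences from the physical 377 mm³.

## Limitations

The simulator is geometric, not physical: no projection physics, beam
hardening, blooming, or detector spectral response, and the base-image
scaling is a calibrated stand-in for the proprietary vendor scaling (only
calcium/iodine separability is modeled). See `docs/methods.md` for the full
model description, parameter defaults, and design choices.
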