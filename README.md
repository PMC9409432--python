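# xylotrace

CT-based phenotyping of wood-borer larval galleries.

Wood-boring beetle larvae — the pine sawyer *Monochamus alternatus*, vector
of pine wilt disease, being the motivating case — excavate galleries hidden
inside trunk xylem. X-ray CT shows these tunnels non-destructively: open
gallery sections are air-filled and dark, frass-packed sections image like
the surrounding wood, and larvae are brighter than xylem. `xylotrace` turns
such volumes into quantitative gallery phenotypes:

* **phantom** — synthetic wood-segment CT volumes with exact voxel-level
  ground truth: ringed trunk, galleries following published per-shape-class
  parameter distributions, frass blockages, larvae, scanner noise;
* **segment** — air-interval thresholding, seeded 3D region growing,
  automatic frass-blockage bridging (reconnecting gallery fragments through
  a frass-attenuation corridor and recording the blocked sub-mask), and
  per-label morphological smoothing;
* **morphometry** — skeleton-based centerlines and the seven standard
  gallery parameters: entrance-hole width, boring depth (radial excursion
  from the pith, estimated per slice from the annual-ring pattern), vertical
  extent, blockage length and volume, total length, boring volume;
* **classify** — C / S / Y gallery typing from branch topology and the
  axial placement of the entrance and emergence holes;
* **stats** — one-way ANOVA (from raw values or exactly from per-group
  n/mean/SE summaries) and Duncan's new multiple range test with compact
  letter displays.

The statistical core, for groups \(i = 1..k\) with sizes \(n_i\), means
\(\bar x_i\) and SDs \(s_i\) (reconstructed from SEs as \(s_i = \mathrm{SE}_i\sqrt{n_i}\)):

$$F=\frac{\sum_i n_i(\bar x_i-\bar x)^2/(k-1)}{\sum_i (n_i-1)s_i^2/(N-k)},$$

and Duncan's step-down range test compares each span of \(p\) ordered means
against \(q^*\!\left(p,\ N-k,\ (1-\alpha)^{p-1}\right)\sqrt{\mathrm{MSW}/n_h}\).

## Worked example

```python
import numpy as np
from xylotrace import PhantomConfig, generate_phantom, segment_volume, measure_all
from xylotrace.classify import classify_gallery

cfg = PhantomConfig(trunk_diameter_mm=90.0, n_slices=120,
                    counts={"C": 2, "S": 1, "Y": 1}, seed=7)
volume, truths, ring = generate_phantom(cfg)   # ~9 cm segment, 4 galleries
mask = segment_volume(volume)                  # labeled galleries + blocked sub-mask
metrics, centerlines, pith = measure_all(volume, mask)
for m in metrics:
    call = classify_gallery(centerlines[m.label], m.vertical_length_mm, label=m.label)
    print(f"gallery {m.label}: {call.type_label}  length {m.total_length_mm:.1f} mm  "
          f"depth {m.gallery_depth_mm:.1f} mm  volume {m.boring_volume_mm3:.0f} mm3  "
          f"blocked {m.blockage_volume_mm3 / m.boring_volume_mm3:.0%}")
```

prints (one line per recovered gallery):

```
gallery 1: C  length 81.9 mm  depth 17.9 mm  volume 3020 mm3  blocked 29%
gallery 2: S  length 114.7 mm  depth 31.3 mm  volume 2811 mm3  blocked 18%
gallery 3: C  length 64.0 mm  depth 15.9 mm  volume 3018 mm3  blocked 30%
gallery 4: Y  length 54.6 mm  depth 18.7 mm  volume 2659 mm3  blocked 8%
```

i.e. every gallery is recovered as one object despite its frass plugs, typed
correctly, and measured within a few percent of the generator's ground truth
(lengths/depths) — the frass-blocked share of each bore, here 8–30%, is
itself a phenotype of larval behaviour.

The same pipeline is scriptable from the shell:

```sh
xylotrace simulate --config phantom.yaml --seed 7 --out vol.nrrd --truth truth.json
xylotrace segment vol.nrrd --out-labels labels.nrrd --out-blocked blocked.nrrd
xylotrace measure vol.nrrd labels.nrrd blocked.nrrd --out metrics.csv
xylotrace stats --metrics metrics.csv --out report.csv
xylotrace pipeline --seed 7 --outdir run/     # full five-segment reference run
```

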