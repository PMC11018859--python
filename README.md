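# hifi — hyperplexed immunofluorescence imaging analysis

`hifi` is a Python toolkit for analysing hyperplexed (cyclic)
immunofluorescence whole-slide images: repeated rounds of antibody
staining, imaging, and elution on one tissue section, merged into a single
45+ channel image and analysed down to single cells and their spatial
organization. It is aimed at imaging groups who scan whole sections (too
large for generic registration tools to hold in memory) and want a
reproducible, scriptable path from per-round OME-TIFFs to annotated cell
tables and spatial statistics.

The package covers:

* **Memory-bounded alignment** — every round is registered to the round-1
  DAPI reference by minimising the squared intensity difference
  `Σ (I_ref(x) − I_mov(T⁻¹x))²` over a coarse-to-fine pyramid with
  sub-pixel refinement (rigid `T ∈ SE(2)` by default, affine optional);
  the transform is then applied to each channel of that round, keeping
  only one full-resolution channel in memory at a time.
* **Autofluorescence removal** — an unstained pre-labeling round is
  registered like any other round and subtracted pixel-by-pixel,
  `out = max(I − s·AF, 0)`, with per-channel exemptions for endogenous
  signals such as GFP; plus rolling-ball background subtraction (75 µm
  ball).
* **Single cells** — external nuclear label maps (or a watershed baseline)
  are overlap-resolved by interior distance maps, filtered at detection
  probability < 0.5, expanded 2.5 µm into cells capped at 1.5× the nucleus
  area, and measured over four zones (nucleus, cytoplasm, whole cell,
  membrane) per marker.
* **Phenotyping** — MFIs clipped at the 99.7th percentile and scaled to
  [0, 1], clustered by a 10×10 self-organizing map, metaclustered
  hierarchically, and annotated by a user-supplied node → cell-type map.
* **Spatial statistics** — composition tables, Shannon diversity
  `H' = −Σ p ln p`, nearest-neighbor distance networks (edge width
  `100/SD`, threshold `median(SD)·0.8`, node sizes 3–70 over <1%–>25%,
  Louvain communities at resolution 1.5), 30 µm cellular neighborhoods
  (k-means, k = 15), and the classical label-permutation interaction test
  (1000 permutations, add-one p values).

A fully seeded synthetic-data module generates every fixture with ground
truth (multi-round images with known transforms, nuclei label maps, marker
mixtures, marked point patterns), so the whole pipeline is testable end to
end without any slide data. See `docs/methods.md` for the models,
parameter defaults, and limitations.

## Worked example

Simulate a 3-round experiment with known inter-round motion and an
autofluorescence round, align it, and score the recovery:

```python
import numpy as np
from hifi.synthetic import FixtureSpec, make_cyclic_rounds
from hifi.align import align_experiment

spec = FixtureSpec(seed=0, shape=(1024, 1024), n_rounds=3, channels_per_round=3)
rounds, af_round, truth = make_cyclic_rounds(spec)
af_map = {f"M{k}_{c}": f"AF_{c}" for k in (1, 2, 3) for c in (1, 2)}
result = align_experiment(rounds, af_round=af_round, af_map=af_map)

print("channels:", result.stack.marker_names)
for k, t in enumerate(result.transforms):
    rec = t.apply_points(truth["landmarks"][k])
    rms = np.sqrt(np.mean(np.sum((rec - truth["landmarks_reference"]) ** 2, axis=1)))
    print(f"round {k+1}: residual={t.residual:.1f}  landmark RMS={rms:.3f} px")
```

```
channels: ['DAPI', 'M1_1', 'M1_2', 'M2_1', 'M2_2', 'M3_1', 'M3_2']
round 1: residual=0.0  landmark RMS=0.000 px
round 2: residual=11415.8  landmark RMS=0.022 px
round 3: residual=11453.2  landmark RMS=0.004 px
```

Each round's DAPI recovers the planted rigid motion to ~0.02 px at nucleus
landmarks (the residual is the mean squared intensity difference left by
shot noise); the aligned stack keeps one DAPI plus the six
autofluorescence-subtracted marker channels, and
`hifi.io.write_hyperplex(result.stack, "aligned.ome.tif", pyramid_levels=3)`
writes it as a tiled pyramidal OME-TIFF with names and pixel size in the
metadata.

Downstream, on an annotated cell table (here: six simulated images in
which tumor cells and tumor-associated macrophages share Neyman–Scott
cluster parents over a T-cell background):

```python
from hifi.spatial import (composition, shannon_index, nn_distances,
                          summarize_distances, build_network, neighborhoods,
                          cluster_neighborhoods, test_interactions, sum_sigval)

comp = composition(cells)
groups = cells.drop_duplicates("image_id").set_index("image_id")["group"]
print("mu H' =", shannon_index(comp, groups)["shannon"].mean().round(3))

net = build_network(summarize_distances(nn_distances(cells)), comp)
prof, types = neighborhoods(cells, radius_um=30)
cn, mean_comp, per_image = cluster_neighborhoods(prof, types, k=3, seed=0)
print(mean_comp.round(2))
print(sum_sigval(test_interactions(cells, n_perm=1000, seed=0))
      .query("type_a=='Tumor' and type_b=='TAM'"))
```

```
mu H' = 1.082
 cn  TAM  Tcell  Tumor
  1 0.23   0.09   0.68
  2 0.01   0.97   0.02
  3 0.52   0.09   0.39
  group type_a type_b  sum_sigval    sum_p  n_images
treated  Tumor    TAM           6 1.000999         6
```

The mean Shannon index over the three cell types is 1.082 (max ln 3 ≈ 1.10,
so the images are near-evenly mixed); the k = 3 neighborhoods separate a
tumor-dominated niche, a T-cell niche, and a TAM-rich mixed niche; and the
interaction test calls Tumor–TAM attraction significant in all six images
(`sum_sigval = +6`), as planted.

A thin CLI wraps the same library calls:

```bash
hifi simulate rounds --out sim/ --seed 3
hifi align --rounds sim/round1.ome.tif --rounds sim/round2.ome.tif \
           --rounds sim/round3.ome.tif --af-round sim/af.ome.tif --out aligned.ome.tif
hifi spatial interactions --cells cells.csv --n-perm 1000 --seed 7 --out interactions.csv
```

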