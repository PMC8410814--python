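# nodeglia

Quantification of microglia–node of Ranvier interactions in two-channel
fluorescence microscopy.

Microglia — the resident immune cells of the central nervous system —
extend highly motile processes that repeatedly touch nodes of Ranvier,
the short unmyelinated axonal gaps where action potentials regenerate.
Quantifying those contacts from imaging data involves a small set of
recurring measurements: how many nodal structures are contacted in a
field, how stable each contact is over a time-lapse movie, how a process
tip moves relative to its starting point, how ramified and how
exploratory a cell is, and — in demyelination models — how myelinated
the tissue is and which activation phenotype the cells express.  This
package implements that measurement suite as a tested, scriptable
library for researchers analysing microglia reporter / nodal marker
imaging (e.g. CX3CR1-GFP or Iba1 against Nav, AnkyrinG or
Nfasc186-mCherry clusters).

## Core definitions

- **Contact** — at least one microglia-positive pixel overlapping or
  juxtaposed to at least one node-positive pixel.  Juxtaposition is a
  configurable pixel adjacency (`face` = 4/6-neighbourhood,
  `full` = 8/26, the default).
- **Contact stability** — for each microglia–node pair over a movie:
  the percentage of frames with contact, and the longest run of
  consecutive frames with (or without) contact.
- **Tip motility** — on origin-relative trajectories, per-step
  Euclidean distances d(tₙ, tₙ₊₁) = √((xₙ₊₁−xₙ)² + (yₙ₊₁−yₙ)²)
  converted to µm; total path length; mean instantaneous velocity in
  µm/min; mean distance from the t₀ origin.
- **Ramification index** — R = (perimeter/area) / (2·√(π/area)):
  1 for a disk, larger for branched cells.
- **Surveillance index** — S = Σ over frame pairs and pixels of
  (process extension + process retraction), i.e. the total count of
  pixels gained or lost between consecutive frames of a binarized
  single-cell movie.
- **Myelination index** — area(myelin ∩ axon) / area(axon) within a
  region of interest; the lesion unremyelinated fraction and
  marker-positive microglia fractions (IGF1⁺ / iNOS⁺) follow the same
  mask-ratio logic.
- **Mean-of-means aggregation** — per-field percentages are averaged
  within each animal, then per-animal means within each condition, so
  n is the number of animals.

Because every one of these numbers depends on segmentation and
adjacency conventions, the package ships a synthetic-microscopy
generator (`nodeglia.synthetic_microscopy`) that builds two-channel
scenes with *exact* ground truth — constructive contact placement,
two-state Markov contact dynamics, free vs confined tip random walks,
Gaussian PSF and Poisson–Gaussian noise — so the whole pipeline can be
validated end-to-end against known answers.

## Worked example

Simulate two conditions (25% vs 60% of nodes initially contacted, the
kind of contrast seen between control and remyelinating tissue),
render, segment, and quantify:

```python
from nodeglia.pipeline import RunConfig, run_pipeline

cfg = RunConfig(n_conditions={"control": 0.25, "remyelination": 0.6},
                n_animals=4, fields_per_animal=4, movie_frames=21)
tables = run_pipeline(cfg, seed=7, outdir="out")
print(tables["condition_summary"].to_string(index=False))
```

```
    condition  mean_percent  sem_percent  n_animals  n1_flag
      control          25.0          0.0          4    False
remyelination          60.0          0.0          4    False
```

The planted contact fractions are recovered exactly at this signal
level (the s.e.m. is 0 because every field of 20 nodes recovers its
planted count).  The same run scores one 21-frame movie per condition
(attach 0.3 / detach 0.1 per 30-s frame, stationary contact probability
0.75) and the planted process tips:

```
               percent_frames_with_contact  longest_contact_run
condition
control                               71.9                 10.7
remyelination                         66.2                 10.6

          mean_distance_from_origin_um  mean_instantaneous_velocity_um_per_min  total_path_length_um
regime
confined                          0.40                                    0.82                  8.18
free                              1.15                                    0.72                  7.22
```

Confined tips (anchored at a node) stay ~3× nearer their origin than
free tips at matched step size — the signature that distinguishes a
held contact from random scanning — while velocity and path length
barely differ.  Every table is also written as CSV next to a
`provenance.json` recording the package version, the full resolved
configuration and its hash.

The same operations are available on real data through the CLI
(`nodeglia contacts`, `nodeglia dynamics`, `nodeglia morpho`,
`nodeglia myelin`, `nodeglia run-all`) on OME-TIFF stacks and track
CSVs; see `nodeglia --help`.

## Layout

- `nodeglia.synthetic_microscopy` — scenes, ground truth, tip walks, rendering
- `nodeglia.masks` — thresholding, nodal-structure labelling, cell extraction
- `nodeglia.contacts` — contact rule, per-field percentages, aggregation
- `nodeglia.dynamics` — contact time series and trajectory metrics
- `nodeglia.morphodynamics` — ramification and surveillance indices
- `nodeglia.myelin_phenotype` — myelination index, lesion and marker fractions
- `nodeglia.pipeline` / `nodeglia.cli` — orchestration, provenance, fixtures

`docs/methods.md` documents the models, parameter choices and
limitations in detail.
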