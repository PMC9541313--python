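# Methods

`prothallus` analyzes cell division dynamics in the apical meristems of fern
gametophytes from time-lapse images of wall-stained tissue, and ships a
cell-based growth simulator that generates ground-truthed synthetic image
series so that every stage of the measurement pipeline can be verified
without microscope data. This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic validation does
and does not establish.

## The tissue model

A gametophyte is represented as a conforming planar subdivision: simple
polygons (cells, coordinates in micrometres) sharing vertices along common
walls (`prothallus.mesh.CellMesh`). A division inserts a chord through the
parent polygon; chord endpoints are inserted into every loop using the
intersected edges, so daughters tile the parent exactly (area is conserved
to machine precision) and the mesh stays conforming. Chord endpoints that
would fall within 2% of an existing vertex snap to it, which prevents
near-duplicate vertices from collapsing into slivers later.

Growth is affine per cell with shared vertices moved to the mean of their
incident cells' wishes. Two regimes matter:

* **Uniform expansion** (every cell carries the same factor, the default
  during simulation): the conforming solution is exact global scaling about
  the tissue centroid. This is applied directly — it cannot fold any cell
  and the tissue expands by precisely `growth_factor` per 48-h window in
  linear dimension.
* **Differential expansion** (unequal factors): the vertex-averaged map can
  fold thin cells, so displacement is damped per offending cell
  (coarse-to-fine, factor halved up to six times) until every polygon is
  simple. The damping factor is recorded per window in the series metadata.

Growth precedes division within a window ("cells grow, a minority divide").
An early design in which only non-dividing cells expanded suppressed
interior expansion through the shared vertices and produced the *inverse*
of the observed size/division relationship; uniform expansion with repeated
halving of meristem cells reproduces it.

## The division grammar

One simulation step is one 48-h window. Probabilities are per cell per
window:

| parameter | meaning | default |
| --- | --- | --- |
| `p_oblique` | apical initial self-renews by oblique division | 0.60 |
| `p_terminate` | apical initial terminates by periclinal division | 0.25 |
| `q1`, `q2` | marginal (packet-upper) cell divides anticlinally / periclinally | 0.15, 0.35 |
| `q3`, `q4` | submarginal (packet-lower) cell divides anticlinally / periclinally | 0.30, 0.10 |
| `p_trichome` | eligible cell initiates a trichome | 0.02 |
| `growth_factor` | linear expansion per window | 1.20 |
| `size_gate` | minimum area (um^2) to divide | 150 |
| `size_max` | differentiation ceiling (um^2): larger cells stop dividing | 600 |
| `apical_fraction` | fraction of directions (about the tissue centroid, centred on the apex) forming the meristem sector | 0.5 |

The `q` defaults are configuration placeholders chosen to reproduce the
qualitative ordering seen in live imaging (upper cells: periclinal >
anticlinal; lower cells: anticlinal > periclinal); they are not published
estimates, which were never printed as numbers in the text they summarize.

Division orientation is constructed from the tissue margin: the margin ring
is resampled at 1 um and tangents smoothed over ~±5 um (identical
definitions in the simulator and the measurement pipeline, which is what
makes constructed and measured orientations comparable). Anticlinal chords
run along the local margin normal through the parent centroid, periclinal
chords along the tangent, oblique chords at 45 degrees. A division whose
chord would leave a daughter thinner than `min_thickness` (5 um) on either
side is skipped and counted in the series metadata; the check measures the
distance from the chord to both extremes of the cell, because a chord
through the centroid of a non-rectangular cell (a corner triangle, say)
does not bisect its extent.

The apical-initial phase runs until a periclinal termination event; a
simulation can also start from an established rectangular sheet
(`initial_sheet=(rows, cols, w, h)`), the configuration used for
experiments on established multicellular meristems. Sheet corners are
chamfered because a cell sitting on a sharp 90-degree corner has no
well-defined margin tangent (real prothalli are rounded).

The size gate plus the differentiation ceiling confine division to small
meristem cells, so dividing cells are smaller on average than grown
non-dividers — the generator's built-in size/division correlation that the
pipeline must recover. Without the ceiling, large cells passing the minimum
gate dominate the divided class and the correlation inverts.

Trichomes initiate by asymmetric division: a marginal cell cuts off a small
(~40 um^2) triangular daughter at its outermost corner, whose apex then
extends ~10 um per window along the margin normal; an inner cell instead
becomes the bearer of an out-of-plane trichome (its in-plane polygon is
unchanged; no division event is logged because none is visible in plane)
and is rendered with a bright wall ring overlying it, as a cone-shaped
trichome appears in a maximum-intensity projection.

## Rendering

Snapshots are rasterized on a common grid (default 0.5 um/px — typical
confocal sampling at this magnification): wall pixels (label boundaries) at
`wall_intensity`, interiors at `interior_intensity`, background at
`background_intensity` (3000/1000/200 by default, 16-bit-like units),
followed by Gaussian optical blur (1.5 px) and seeded additive noise
(sd 150). A 20-px background margin surrounds the tissue; segmentation
estimates the background level there. The rasterized ground-truth label map
(dense labels, with a label-to-cell table) accompanies every image.

## Segmentation

Marker-controlled watershed:

1. *Tissue mask*: two-stage Otsu on a strongly smoothed copy (walls vs
   rest, then tissue vs background, with a floor at a quarter of the wall
   cut so noise cannot cross), closing, hole filling, speck removal, then
   2 px erosion so the rim sits near the outer wall crest.
2. *Walls*: white top-hat (disk radius 5 px) + Otsu within the mask —
   detects thin bright ridges independent of local background.
3. *Seeds*: h-maxima (depth 1 px) of the smoothed (sigma 1.5 px) distance
   transform of the non-wall tissue; any enclosed interior compartment the
   maxima missed gets one seed (thin cells), except compartments touching
   the mask rim (the outer blur slope).
4. Watershed of the wall probability from the seeds.
5. *Rim re-growth*: the flooding reaches the outer wall crest — an
   intensity plateau — from whichever basin gets there first, which lets
   one cell run a thin flange along its neighbours' outer walls and steal
   their margin contact.  The outer 3 px rim band is therefore vacated and
   re-grown by proximity, giving every cell its own stretch of margin.
6. Regions below `min_cell_area` (20 um^2) merge into the neighbour with
   the longest shared boundary.

Everything is deterministic for a fixed image and configuration.

## Tracking and division detection

Consecutive label maps are aligned by a similarity transform: isotropic
growth is estimated as sqrt(area ratio) of the tissue masks and divided
out, then centroids are aligned and rotation grid-searched (±30 degrees at
1 degree, refined at 0.1 degrees). Strictly rigid alignment leaves
peripheral cells displaced by up to a cell diameter at the simulated growth
rate, which is why the scale term exists. Because tissue growth is not
perfectly isotropic (the meristem barely expands while mature regions do),
a residual displacement field is corrected coarse-to-fine by block-wise
phase correlation on the label-boundary images (2x2, 4x4, 8x8 tiles, shift
caps scaling with tile size so a fine tile cannot lock onto the wrong wall
of the quasi-periodic wall grid).

Each later cell is assigned to the earlier cell containing the largest
fraction of its back-transformed area (ties to the smaller label). A parent
divided when at least two children overlap it at fraction >= 0.5 *and* each
holds >= 10% of the strong children's combined area (the share guard
rejects sub-resolution fragments masquerading as daughters); the two
largest strong children define the new-wall interface. Children with
best overlap < 0.25 are reported unmatched, never silently attached.
When the start-frame wall-probability image is available, a candidate
division whose daughter interface already shows a wall at the window start
is rejected — a new wall cannot pre-date its window, so such candidates are
segmentation merges or older divisions.

Orientation of a detected division: the interface pixels between the two
daughters are mapped back to start-frame coordinates, their principal
direction is compared with the margin tangent at the vertex nearest the
wall midpoint (falling back to the parent centroid when no wall pixels
were found — the wall is more local than the centroid for large or
irregular parents); > 60 degrees anticlinal, < 30 degrees periclinal,
oblique between (configurable, symmetric about 45 degrees). Oblique calls
are excluded from anticlinal/periclinal rate statistics but retained in
event tables. Trichome-initiating asymmetric divisions in the simulator
have no prescribed axis, so their truth orientation is likewise recorded
from the constructed wall's actual angle to the margin.

Layers: marginal cells share boundary with the margin of the non-trichome
tissue; submarginal cells touch a marginal cell; the rest are inner. Across
consecutive windows the bookkeeping rule applies: a daughter added inward
by a *submarginal* cell's periclinal division is demoted from the
submarginal layer in the following window (daughters added inward by
marginal periclinal divisions are classified submarginal by the geometric
rule itself).

Packets: two adjacent rectangular marginal cells plus one rectangular
submarginal cell adjacent to both; rectangularity = solidity >= 0.9 and
minimum-area-rotated-rectangle fill >= 0.8 (operationalizations of
"rectangular"; recorded in output manifests). Overlapping candidates are
resolved greedily by mean rectangularity; a cell joins at most one packet.
Packet division types: I/II = anticlinal/periclinal division of an upper
cell, III/IV = of the lower cell; any member dividing more than once makes
the packet complex and excludes it from the type statistics.

## Statistics

The unit of replication is the time-lapse set; SE = SD(ddof=1)/sqrt(n)
across sets. "Student's two-tailed t-test" is the pooled-variance
two-sample t (Welch behind a flag). Per-packet percentages divide type
counts by cells at risk (2 for I/II, 1 for III/IV) x 100, so totals across
types can exceed 100%. Layer rates divide events by cells in the layer at
the window start, normalized x(48/timeframe) for 24-h windows. Within
dividing cells, orientation fractions divide by all a+p events of the
layer; multi-divider cells contribute every event. Undefined per-set values
(empty layer, no events) are dropped listwise with counts reported.
Whole-gametophyte growth rates are area(48 h)/area(0 h), trichomes
excluded, compared between stain and mock groups by the same t-test.

## Validation studies and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`) run five studies:

1. **Segmentation**: 20 sheet-grown snapshots (~50-80 cells each, default
   noise, and noiseless) matched one-to-one against truth at IoU >= 0.7.
2. **Division detection**: 30 simulated 48-h windows; precision, recall and
   orientation accuracy against the simulator's event log.  Scoring is per
   series across its windows: a division whose fresh wall is below optical
   resolution at its window's start is necessarily detected one window
   later (the same images offer a human analyst no more information), and
   the evaluator matches such late detections to their events through the
   lineage instead of double-counting them as a false positive plus a miss;
   late detections of events before the evaluated span are excluded from
   scoring.
3. **Equation oracle**: the three percentage operations vs independent
   brute-force recounts on 1000 random event tables (exact agreement).
4. **Rate recovery**: 30 one-window sheets with marginal periclinal
   probability 0.30 and submarginal 0.05 per 48 h (`size_max` disabled so
   the probabilities apply to every cell); pooled pipeline estimates must
   fall inside the binomial 95% CI, and the marginal-submarginal difference
   must be detected at p < 0.01 across sets. As in time-lapse practice,
   the analysis region is the central 70% of each sheet's long axis — the
   distal tips are excluded, mirroring studies that quantify a marked
   region of the tissue.
5. **Size vs division**: five sheets grown five windows under the default
   size-gated rules (~150 cells each at measurement); start-of-window areas
   of divided vs non-divided cells, pooled across samples.

Problem sizes were chosen so the whole battery runs in a few minutes on a
single core while keeping every estimate's sampling error well below the
effects being checked.

## What the synthetic validation does not show

The generator emulates flat one-cell-thick polygonal tissue with clean
walls, stationary illumination, isotropic-plus-local growth and rigid
repositioning between sessions. It does not emulate out-of-focus Z-bleed,
uneven staining, wall brightness that varies with wall age, elastic tissue
deformation, or segmentation-relevant debris — so passing these studies
shows the pipeline's logic and numerics are correct, not that its default
thresholds are optimal for any particular microscope. Rule-based trichome
flagging (convex-hull protrusion + aspect ratio) is only well-posed for
isolated protrusions on a large tissue: with several neighbouring
trichomes each spike lies inside the hull spanned by the others. Synthetic
studies therefore use ground-truth trichome flags (truth mode), and the
geometric rule is verified on constructed single-protrusion tissue.

## Known limitations

* No tissue mechanics: expansion is kinematic; wall tension, pressure and
  stress-oriented division are outside scope.
* The simulator's margin-tangent frame is ambiguous exactly at strong
  margin corners; chamfered sheet corners mitigate but do not remove this,
  which is why the rate-recovery study, like its real-world counterpart,
  restricts analysis to a marked region.
* Division detection degrades when segmentation merges freshly divided
  thin daughters; the residual ~3-5% miss rate is the dominant error of
  the rate estimates.
* 96-h series are always decomposed into consecutive 48-h windows and
  composed via lineage links, never matched end-to-end.
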