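# Methods

## The thickness statistic

A lipid's membrane thickness is the average of its *k* = 3 shortest
trans-leaflet headgroup distances: full 3D Euclidean distances from the
lipid's headgroup particle to phosphate-bearing headgroups of the opposing
leaflet, with the minimum-image convention applied to the lateral axes only
(the membrane normal, fixed to *z*, is never wrapped).  Leaflets are split
per frame by the sign of *z* about the global midplane (median headgroup
*z*); headgroups within 0.5 nm of the midplane are flagged as outliers but
still labeled.  Cholesterol carries a hydroxyl-proxy particle: it
participates in leaflet assignment and density grids but is excluded from
the thickness statistic on both ends (no phosphate).  If the opposing
leaflet holds only *m* < *k* phosphate lipids, *m* distances are averaged
and recorded in `k_used`.

Maps pool per-lipid samples over frames onto a 0.2 nm lateral grid; empty
cells are missing (NaN), never zero, and the count-weighted grid mean equals
the pooled sample mean by construction (checked on every map).
`leaflet_scope` restricts which leaflet's headgroup *positions* populate the
grid while the value mapped remains the total (trans-leaflet) thickness —
this mirrors the convention of per-leaflet thickness maps that color one
surface by the distance between both surfaces.  As a supplementary
per-leaflet measure, reports also carry mean |z − midplane| leaflet heights
for the defect zone versus the bulk; neither measure is privileged.

### Estimator bias

On a flat bilayer the statistic is biased high by construction: only the
directly opposing lipid sits at the true separation *d*; the other
nearest neighbors sit at lattice offsets *s*, contributing
√(d² + s²) > d.  For an aligned square lattice the closed-form value is
(d + 2√(d² + s²))/3 — e.g. 4.2503 nm at d = 4.2 nm, s = 0.8 nm — and the
bias at a planted defect floor *f* approaches (2/3)(√(f² + s²) − f) for
defects much wider than the lattice spacing.  The synthetic defaults (below)
keep this bias within the ±0.15 nm recovery tolerance asserted by the
acceptance suite; it is a property of the estimator, not an artifact of the
implementation, and would shrink with real (denser, disordered) headgroup
distributions.

## The synthetic bilayer generator

The generator emulates only what the analyses consume: headgroup geometry.
Each leaflet is a square lattice of single headgroup particles (one per
lipid; P for phospholipids, O3 for cholesterol) at ±separation/2 about the
box midplane, with Gaussian lateral and vertical jitter refreshed
independently every frame.  Species are assigned once per leaflet by
largest-remainder allocation of the composition over the lipid count (ties
broken by larger fraction, then name) and randomly permuted over sites.

A thinning defect pulls the headgroup planes toward the midplane with a
lateral Gaussian profile of width σ; the total deformation depth is
separation − floor, split between leaflets by `leaflet_share` (1.0 = all of
it carried by the upper/cytosolic leaflet).  With jitter off, the planted
total thickness at any lateral point is available in closed form
(`planted_thickness`) and the analysis modules are tested against it.

A protein stand-in contributes labeled helix axes (six per protomer,
arranged so TM2/TM5 and TM1/TM6 are spatially adjacent pairs, as in the
rhomboid fold where TM2–TM5 forms the lateral gate); lattice sites within
the exclusion radius of any axis carry no lipid, and each axis carries four
backbone pseudo-residues (N, CA, C, O beads with small per-frame wobble) so
the conformational analyses have protein atoms to work on.

What the generator deliberately does **not** emulate: acyl chains, water,
ions, curvature and undulations, lipid diffusion and temporal correlation
(frames are independent — the maps pool frames, so correlation is
irrelevant to them), protein conformational substates, and chromatogram
noise.  Passing tests therefore demonstrate correctness of the *analyses*
against known geometry, not fidelity of any physical model; on real MD
output the same code paths apply unchanged via the PDB/GRO readers.

### Presets

| preset | defect floor (nm) | σ (nm) | upper-leaflet share |
|---|---|---|---|
| ER_BULK | — (no defect, no protein) | — | — |
| DFM1_WT | 2.25 (gate midpoint TM2–TM5) | 3.0 | 0.5 |
| DFM1_F107S | 3.25 | 3.0 | 1.0 (luminal leaflet spared) |
| DFM1_QUAD | 4.2 (= separation: thinning ablated) | 3.0 | 0.5 |
| DERLIN1_TETRAMER | 3.5 (periphery, TM1–TM6 of protomer A) | 2.5 | 0.5 |

Floors are the midpoints of the thickness ranges observed for each
condition; the quad mutant's nominal midpoint (4.25 nm) exceeds the
unperturbed separation, so its defect is capped at the separation — a
zero-depth defect, i.e. thinning fully ablated, which is what that mutant
shows.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| box | 10 × 10 | nm | patch size of the emulated systems |
| leaflet separation | 4.2 | nm | puts the 3-NN bulk readout mid-range of a 4.0–4.5 nm phospholipid bilayer |
| area per lipid | 0.50 | nm² | cholesterol-condensed end of ER-mixture values; the denser lattice keeps the estimator's lateral-shell bias small relative to the ±0.15 nm recovery tolerance |
| lateral/vertical jitter SD | 0.05 | nm | sub-Å positional disorder; enough to decorrelate frames without washing out planted geometry |
| n_frames | 50 | — | pooled sampling depth; maps are stable and the whole pipeline stays in seconds |
| map bin size | 0.2 | nm | ~2 bins per lattice spacing; stable cell occupancy on a 10 nm patch |
| smoothing σ | 1 | bins | minimal denoising before taking the map minimum |
| bulk radius | 2.5 | nm | separates the protein-proximal zone from bulk on a 10 nm patch |
| defect σ | 2.5–3.0 | nm | protein-footprint-scale funnels, wide relative to the 0.71 nm lattice spacing (see estimator bias) |
| k | 3 | — | definition of the statistic |
| cluster cutoff | 0.1 | nm | conventional GROMOS-clustering default; not stated by the study, configurable |
| SASA probe / points | 0.14 / 960 | nm / — | water-probe radius; quadrature already ~1e-3 nm² accurate |
| voxel size | 0.1 | nm | hard-sphere (nearest-voxel) binning, VMD-volmap-like |
| read error rate | ≤ 0.05 | per base | Sanger-scale substitution errors; no quality model |

Every default is surfaced as a config key / CLI flag.

## Numerical and design choices

- **Units:** nm internally everywhere; Å only at the PDB boundary (×10
  exactly).  Orthorhombic boxes only; triclinic input is rejected with a
  clear error.  0-based atom indices internally; residue numbering is
  preserved from input.
- **Leaflet midplane** is the global per-frame median; no local-midplane
  fitting — the patches are small and pre-centered.
- **Smoothing** is count-weighted Gaussian filtering with periodic wrap;
  NaN cells contribute zero weight and stay NaN where unsupported.
- **Density occupancy** is the fraction of frames in which a voxel holds at
  least one selected atom (binarized per frame), so it is always in [0, 1];
  raw counts are kept separately and conserve the selection exactly.
- **Clustering** follows the Daura iteration: repeatedly extract the
  unassigned frame with the most neighbors within the cutoff (ties →
  lowest frame index) together with its neighbors.
- **SASA** uses a deterministic golden-spiral point set; reflections are
  excluded in Kabsch superposition by the usual sign correction
  (determinant +1); superposition accepts n ≥ 2 points, with degenerate
  configurations handled by the SVD.
- **Aligner:** unit-cost semi-global DP (read fully aligned, reference
  end-gaps free); among co-optimal alignments the leftmost end is taken and
  the traceback prefers matches over gaps, so outputs are deterministic.
  Reads whose edit distance exceeds 10% of their length are rejected.
- **Screen filters:** "one point mutation" is interpreted at the nucleotide
  level; a single silent substitution is accepted as a candidate but
  labeled `silent` (labeling preserves information).  Indels disqualify.
  Strand verification is strict by default — a call must appear identically
  in both reads; positions covered by one read only can be verified under
  the lenient policy.  Amino-acid labels use 1-based protein numbering
  ("F107S"); nucleotide coordinates are 0-based half-open.
- **Headgroup selection** maps residue names to headgroup atom names
  (phospholipids → P, cholesterol → O3); standard amino-acid residues are
  ignored as protein, unknown lipid-like residues are reported in an
  "unclassified" list, and lipids missing their named atom are reported,
  never silently dropped.

## Problem sizes

The shipped drivers and acceptance checks use 50-frame, ~190-lipid-per-
leaflet patches (≈ 390 headgroup particles plus 96 protein-stub atoms),
200-clone read batches on a 336-nt toy ORF, and ≤ 8-frame matrices for the
exhaustive clustering oracle — sizes at which every stage completes in
seconds while leaving the statistics stable.

## Known limitations

- The generator's flat-plane + Gaussian-defect geometry cannot probe
  curvature-coupled effects, leaflet interdigitation, or lipid sorting
  around the protein; conclusions about those require real trajectories.
- The 3-NN statistic's lattice bias (above) means planted floors are
  recovered to ~0.1 nm, not exactly; tests assert the ±0.15 nm envelope.
- The protein stand-in has no side chains, so SASA and clustering exercise
  the algorithms rather than reproduce protein-specific values; the
  tetramer's "~50% top-cluster prevalence" style of observation is out of
  reach of a single-substate stub.
- The mutation caller handles substitutions rigorously but treats any indel
  as disqualifying; it does not model Mutazyme mutational spectra, read
  quality, or chromatogram artifacts.
- APBS-style surface electrostatics and figure rendering are outside the
  package's scope.
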