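# derlintools

Analysis toolkit for studying how derlin rhomboid pseudoproteases (yeast
Dfm1, human Derlin-1) distort the ER membrane, together with the sequence
analysis behind a random-mutagenesis retrotranslocation screen.  Everything
is driven by a ground-truthed synthetic generator, so the full pipeline runs
on a laptop with no MD engine, no downloads and no wet-lab data.

It is aimed at structural bioinformaticians and membrane-protein groups who
want a tested, reusable implementation of:

- **per-lipid trans-leaflet thickness** — for lipid *i* with headgroup
  position **r**ᵢ, thickness is the mean of the *k* = 3 smallest distances
  ‖**r**ᵢ − **r**ⱼ‖ to phosphate headgroups *j* of the opposing leaflet
  (3D Euclidean, minimum-image in *x,y* only; cholesterol, which has no
  phosphate, is excluded from the statistic but not from leaflet
  assignment);
- lateral **thickness maps** (0.2 nm bins, samples pooled over frames),
  bulk statistics and **thinning reports** that locate the smoothed minimum
  in the protein-proximal zone;
- time-averaged 3D **headgroup density grids** with OpenDX export;
- **GROMOS (Daura) conformational clustering** on backbone pairwise RMSD
  (Kabsch superposition) and **Shrake–Rupley SASA** (1.4 Å probe,
  deterministic golden-spiral quadrature);
- the mutagenesis screen's **mutation caller**: semi-global read alignment
  to a wild-type ORF, strand-verified substitution calls, and the candidate
  filters (exactly one point mutation, no premature stop, verified on both
  strands, outside the excluded SHP-tail region);
- a **synthetic data generator**: mixed ER-composition bilayer patches
  (47% POPC / 20% POPE / 15% cholesterol / 11% POPI / 7% POPS, 10 × 10 nm)
  with planted Gaussian thinning defects and a TM-helix protein stand-in,
  plus paired Sanger-style reads with planted substitutions.

## Worked example

```python
import derlintools as dt

spec = dt.build_bilayer_spec("DFM1_WT")       # planted 2.25 nm gate defect
traj = dt.generate_trajectory(spec, seed=11)  # 50 frames, ~190 lipids/leaflet
tmap = dt.thickness_map(traj, bin_size=0.2)
report = dt.thinning_report(tmap, spec.protein)
print(f"min {report.min_thickness:.3f} nm at {report.min_location},"
      f" nearest helices {report.nearest_helices[:2]}")
print(f"bulk {report.bulk_mean:.3f} nm")
```

prints

```
min 2.387 nm at (5.9, 5.9), nearest helices [('TM2', 0.581), ('TM5', 0.762)]
bulk 3.578 nm
```

i.e. the map's smoothed minimum recovers the planted 2.25 nm floor (the
3-nearest statistic carries a small positive lattice bias) and localises it
between the TM2 and TM5 helix axes — the lateral-gate region.  The "bulk"
value for this patch is pulled below the unperturbed 4.2 nm separation by
the wide defect tail; a defect-free ER patch reads ≈ 4.22 nm.

The same pipeline is scripted end-to-end in `analysis/01…05` (simulate →
thickness maps → density grids → clustering/SASA → mutation screen), each
writing its tables under `results/`, and is also exposed as a CLI:

```bash
derlintools full --preset DFM1_WT --seed 1 --out run_out
derlintools screen --reference-fasta wt.fasta --reads-fasta reads.fasta --out screen_out
```

## Layout

```
src/derlintools/   library: synthetic, structio, thinning, density,
                   conformation, screen, cli
analysis/          numbered narrative drivers writing results/
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    model, parameters, estimator properties, limitations
```
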