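# lcbsr

Binding-site identification for highly flexible ligands from blind-docking
output, by per-residue **L**igand **C**ontact **B**ased **S**coring of
**R**esidues (LCBSR), plus construction of the refined-docking grid box.

## The problem

Very flexible ligands (long isoprenoid chains such as solanesol, with ~25
rotatable bonds) rarely form a single tight cluster when docked blindly
against a whole protein surface, so the usual cluster-based binding-site
call fails. Instead of clustering, this package scores every receptor
residue by how often the docked conformations touch it favorably:

```
LCBSR(r) = log(NCo − NCl) − log(NH / CCl)
```

where, for residue *r* over all poses in an energy tier:

* `NCo` — number of contact events (atom pairs with van der Waals overlap
  `Σr_vdW − D ≥ −0.4 Å`),
* `NCl` — number of clash events (overlap `≥ 1.0 Å`),
* `NH`  — number of hydrogen bonds (donor–acceptor `≤ 3.5 Å`, hydrogen–
  donor–acceptor angle `≤ 30°`),
* `CCl` — number of poses in which *r* clashes at least once.

Poses are grouped into nested tiers by predicted binding energy
(`< −2.0`, `< −3.0`, `< −4.0` kcal/mol); per-tier scores are summed, so
residues touched by the best-energy poses are up-weighted. Scores from
independent docking experiments are added, and residues that appear in too
few experiments are discarded. The top residues define the binding site:
their center of geometry becomes the grid center and the smallest even-npts
AutoDock box (0.375 Å spacing) that contains them becomes the refined-
docking search box.

The package consumes docking output (AutoDock DLG, multi-model PDBQT/PDB
plus an energy table); it does not run a docking engine.

## Worked example

Generate the synthetic demo set (a toy 4-residue receptor and three
blind-docking experiments whose contacts, clashes, H-bonds and energies are
known by construction), score it, and build the site:

```sh
lcbsr fixtures --out-dir demo --seed 0
lcbsr score --receptor demo/receptor.pdb \
            --ensemble demo/exp1.dlg --ensemble demo/exp2.dlg \
            --ensemble demo/exp3.dlg --out-dir demo/out
```

```
INFO lcbsr: receptor: 4 residues, 20 atoms
INFO lcbsr: ensemble exp1: 6 poses; tier sizes [5, 4, 3] at thresholds (-2.0, -3.0, -4.0)
...
INFO lcbsr: wrote demo/out/scores.tsv (2 residues)
```

`demo/out/scores.tsv`:

```
residue  chain  resnum  icode  resname  score_exp1  score_exp2  score_exp3  presence  final_score
ALA-1    A      1              ALA      8.794825    8.794825    8.794825    3         26.384475
GLY-2    A      2              GLY      7.454720    7.454720    7.454720    3         22.364160
```

ALA-1 interacts with poses in all three energy tiers (per-experiment score
ln 15 + ln 20 + ln 22 = 8.7948) and GLY-2 only through poses below
−4 kcal/mol (3 × ln 12 = 7.4547). A third residue planted in just one
experiment is removed by the presence filter (`presence ≥ 2` of 3). Then:

```sh
lcbsr site --scores demo/out/scores.tsv --receptor demo/receptor.pdb \
           --mode top_k --top-k 2 --out-dir demo/out
```

```
INFO lcbsr: site: 2 residues; center (15.000, 0.000, 7.000); npts (80, 2, 60); spacing 0.375
```

which writes `site_report.json`, an autogrid GPF fragment
(`npts 80 2 60`, `gridcenter 15.000 0.000 7.000`, `spacing 0.375`) and a
Vina-style config (`size_x = 30.000` Å = 80 × 0.375, etc.).

The same pipeline is available as library calls
(`read_pose_ensemble → assign_radii → score_experiment →
aggregate_experiments → select_residues → build_grid`); see
`docs/methods.md` for the model details and parameter semantics.

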