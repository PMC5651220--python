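# Methods

## Model

The method treats a blind-docking run as a statistical sample of ligand
placements rather than something to cluster. For each receptor residue *r*
and each pose, every ligand-atom/receptor-atom pair is classified by its
van der Waals overlap

    overlap(i, j) = r_vdW(i) + r_vdW(j) − D(i, j)

into *contact* (`overlap ≥ −0.4 Å`, near-touching), *clash*
(`overlap ≥ 1.0 Å`, sterically impossible) or neither. The two classes are
disjoint — a clash is not also a contact — so that `NCo − NCl` remains an
interpretable "net favorable proximity" count; a flag
(`clash_also_contact`) switches to overlapping classes. Hydrogen bonds use
the standard geometric criterion: donor and acceptor are N or O, heavy-atom
distance ≤ 3.5 Å, and, when the donor carries an explicit hydrogen, the
angle at the donor between donor→hydrogen and donor→acceptor ≤ 30°.

Per residue and energy tier the four operands are accumulated over all
poses in the tier — `NCo`, `NCl`, `NH` as pair/bond *events*, `CCl` as the
number of poses with ≥ 1 clash — and combined as

    LCBSR(r) = log(NCo − NCl) − log(NH / CCl).

A high score means many favorable contacts, few clashes relative to the
number of clashing poses, and (through the second term) H-bond capability;
`−log(NH/CCl)` rewards residues whose clashes are concentrated in few
poses. Tiers are *nested* pose subsets with strict thresholds
(`binding_energy < −2.0, −3.0, −4.0` kcal/mol by default), so a residue
contacted by strongly binding poses accrues the term up to three times.
Per-experiment scores are summed across independent docking experiments
and residues present in fewer than `min_presence` experiments are dropped.

The selected residues' unweighted mean coordinate (center of geometry, not
center of mass) becomes the grid center, and the box is the smallest
even-`npts` grid at the given spacing containing every selected atom
center plus padding — even `npts` being the autogrid convention.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `contact_cutoff` | −0.4 | Å overlap | contact threshold (inclusive) |
| `clash_cutoff` | 1.0 | Å overlap | clash threshold (inclusive) |
| `hbond_da_max` | 3.5 | Å | donor–acceptor heavy-atom distance |
| `hbond_angle_max` | 30.0 | degrees | hydrogen–donor–acceptor angle at the donor |
| `include_hydrogens_in_contacts` | true | — | hydrogens take part in contact/clash counting |
| tier thresholds | −2.0, −3.0, −4.0 | kcal/mol | strict (`<`) nested pose filters |
| `log_base` | natural | — | base-10 selectable; natural keeps summed scores on the familiar 0–25 scale |
| `degenerate_policy` | undefined | — | see below; `pseudocount` adds 1 to NH and CCl |
| `min_presence` | 2 | experiments | presence filter (set to the experiment count for the strict "all experiments" reading) |
| `spacing` | 0.375 | Å | grid point spacing |
| `padding` | 0.0 | Å | extra half-extent per axis; 0 means the box exactly fits atom centers |

Van der Waals radii come from a bundled Bondi-style element table
(C 1.70, N 1.55, O 1.52, H 1.20, S 1.80 …), overridable by a plain-text
`ELEMENT RADIUS` file; docking tools differ slightly in their internal
radii, so small count differences against other software are expected.

## Numerical and degenerate-input choices

* **Degenerate operands.** `log` is undefined when `NCo − NCl ≤ 0`,
  `NH = 0` or `CCl = 0`. Such a tier term is *undefined*: it contributes 0
  to the experiment score and the residue is flagged; silent ±∞ never
  propagates. The optional pseudocount mode (`NH+1`, `CCl+1`) keeps
  clash-free or H-bond-free residues scoreable; `NCo − NCl ≤ 0` stays
  undefined in both modes. A consequence of the default worth knowing: a
  residue that never clashes (`CCl = 0`) cannot receive a defined score.
* **Presence.** A residue "appears" in an experiment when at least one of
  its tier terms there is defined. A defined term of exactly 0 (the
  `NCo − NCl = NH/CCl = 1` identity) still counts as appearing, since it
  reflects observed interaction.
* **Donor typing.** Donors are N/O atoms with ≥ 1 explicit hydrogen within
  1.25 Å (same residue for receptor atoms). When a molecule carries no
  explicit hydrogens at all — common for docking files with merged
  non-polar hydrogens — its N/O atoms fall back to the distance-only
  criterion and the reported bond has no hydrogen/angle. A molecule that
  has hydrogens uses strict typing throughout: an unprotonated N/O there
  is an acceptor only.
* **Boundaries.** Both overlap thresholds are inclusive (`≥`); tier
  thresholds are strict (`<`), so a pose at exactly −2.0 kcal/mol is in no
  tier. `npts` is rounded *up* to the next even integer, never below 2.
* **Ties.** Score-table rows with equal final score order by chain then
  residue number; `top_k` selection keeps all residues tied at the cutoff.
* **Equivalence of the fast path.** The k-d-tree neighbor search is an
  optimization only; it is required (and tested) to agree exactly with the
  exhaustive all-pairs double loop.
* **Altlocs / waters.** First altloc kept; waters (HOH/WAT/…) stripped on
  read by default; other heteroatom residues are retained and scored like
  residues unless excluded. No superposition is performed: all poses of an
  experiment are assumed to share the receptor frame, as docking output
  does.

## Synthetic data

The fixture generator builds what the method needs to be verifiable, not a
realistic protein: residues with an N–CA–C–O(–H) atom pattern placed 30 Å
apart with 6 Å between atoms inside a residue, so every receptor atom's
interaction sphere (≤ ~4 Å) is independent, and ligand atoms placed at
exact overlaps (+0.3 Å for a contact, +1.3 Å for a clash, 2.9 Å
donor–acceptor with collinear H for an H-bond) in directions perpendicular
to the residue axis. Event counts, tier membership (energies are
prescribed, never sampled) and therefore every score are known in closed
form. The H-bond geometry necessarily also registers contacts (donor and
hydrogen both sit within the acceptor's contact window), and the
generator's expected-count bookkeeping includes them.

What passing these tests shows: the arithmetic, geometry criteria, tiering,
aggregation and box construction are implemented exactly. What it does not
show: anything about real protein geometry — crowded residues whose
interaction spheres overlap, alternate conformations, metal sites, or
whether the published cutoffs are chemically optimal. Demo problem sizes
(4 residues, 3 × 6 poses; random sweeps of 3–10 residues and 20–50 ligand
atoms over ~100 seeds) were chosen as the smallest sets that exercise every
tier, the presence filter and all three event types.

## Known limitations

* No π-stacking or hydrophobic-interaction typing; the score uses contacts,
  clashes and H-bonds only.
* PDB/PDBQT parsing covers ATOM/HETATM/MODEL records and AutoDock atom
  types; mmCIF is out of scope, as are protonation and charge assignment.
* The residue-selection threshold has no universal default; `mean` mode is
  the default and `top_k`/absolute modes are provided, since the right
  cutoff depends on the score distribution of the system at hand.
* With two completely hydrogen-free molecules, the distance-only H-bond
  fallback reports each close N/O–N/O pair in both donor directions.
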