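# Methods

## Förster rate network

The transfer rate between two chlorophylls is computed in the point-dipole
approximation, `K_DA = C·κ²/(n⁴R⁶)` with
`κ² = [û_D·û_A − 3(û_D·R̂)(û_A·R̂)]²`. The transition dipole of each
chlorophyll is approximated by the unit vector from its N_B to its N_D
pyrrole nitrogen; `R` and `R̂` are taken from the Mg–Mg separation. Both
conventions matter only up to sign for κ², so the N_B→N_D orientation and the
Mg(donor)→Mg(acceptor) direction are fixed purely for reproducibility of
intermediate vectors.

The formula as used in the light-harvesting literature is dimensionally
ambiguous: `C = 32.26` carries no stated units. We adopt the convention of
the algorithm this constant originates from — `R` in nm, `K_DA` in ns⁻¹ — and
keep all coordinates and the cutoff in Å, converting inside `fret_rate`. A
canonical pair (κ² = 1, R = 2.0 nm) then transfers at
32.26/(1.55⁴·2⁶) ≈ 0.0873 ns⁻¹, which the test suite pins as hand-checked
arithmetic. Users needing a different convention can rescale via
`FretParameters.c_factor`.

Defaults: `C = 32.26`, `n = 1.55`, cutoff 20 Å **inclusive** (a boundary must
be deterministic; a pair at exactly 20 Å is connected). Only
chl a → chl a pairs are connected because the overlap constant involving
chl c is not established; chl c molecules remain in the network as isolated
nodes so their sites are still visible in exports. The pair rule is
extensible (`pair_rule="custom"` with per-pair constants) for users who have
their own overlap estimates. Edges are stored undirected with one symmetric
rate, since C is identical in both directions for a like pair.

Network construction uses a k-d tree over Mg centers with a tiny (1 + 1e-12)
slack on the query radius so that exactly-at-cutoff pairs survive floating
point; an explicit `separation ≤ cutoff` test then decides membership. A
brute-force double-loop enumeration ships alongside as the test oracle.

When two networks are compared under a site correspondence, matched edges are
classified `equal` when the rate ratio is within 5% of unity — below the
rate jitter that coordinate uncertainty at typical cryo-EM resolutions
induces through the R⁻⁶ dependence — and `increased`/`decreased` otherwise.

## Superposition and subunit shifts

Rigid fits are closed-form least squares (Kabsch-type, solved through
scipy's quaternion-based `align_vectors`) over paired Cα atoms; pairing is by
author residue number under an explicit user chain map (species differ in
chain naming; an optional per-chain numbering offset is supported, and no
sequence alignment is attempted). Collinear or < 3-point pairings are
rejected because the rotation is not unique there.

Published antenna-shift values rarely state their protocol. The package's
documented choice: fit the transform on the conserved core only (PsaA/PsaB
for PSI, D1/D2/CP43/CP47 for PSII), with the subunit under test excluded
from the fit, then report (a) the displacement of the subunit's Cα centroid
and (b) the per-atom Cα RMSD, both over the paired atoms. Centroid
displacement was chosen over helix-endpoint measures because it is defined
for every subunit and insensitive to pairing gaps; exact agreement with
figures measured on individual helices is therefore not guaranteed, and the
core RMSD is reported with each shift so discrepancies are attributable.

Cofactor binding sites are matched across models by greedy nearest-first
one-to-one assignment of representative centers (chlorophylls: the Mg atom;
other cofactors: their heavy-atom centroid) within a 3.0 Å match radius —
below typical inter-pigment spacing, above modelling jitter — with
deterministic tie-breaks on site identifiers. On well-separated sites greedy
matching coincides with the Hungarian optimum, which the tests verify against
`scipy.optimize.linear_sum_assignment`.

## Water shells and conservation

A shell is the set of waters whose O atom lies within `shell_radius`
(default 8 Å, inclusive) of any heavy atom of the target residues — the
nearest-atom reference reads "in the vicinity of the clusters" most
naturally, but a per-target centroid reference is available as a parameter.
Conservation against another (superposed) model is again greedy
nearest-first one-to-one matching, conserved meaning a counterpart within
`match_radius` (default 1.2 Å, the typical positional uncertainty of an
ordered water at ~2 Å resolution). Because published conserved-water counts
depend on an unstated threshold, the reporting layer supports sweeping the
match radius; counts are monotone non-increasing as the radius shrinks,
which is property-tested.

## Structure I/O and classification

Parsing and writing go through gemmi (mmCIF/PDB, gzip-transparent). Author
chain identifiers and residue numbers are the canonical site labels, matching
how sites are named in the literature (e.g. "a306/i"). Zero-occupancy atoms
are dropped; alternate locations resolve to the highest-occupancy conformer
with ties broken by the lexicographically first alt_id, so all downstream
geometry is deterministic. Category assignment is a pure function of the
chemical-component code through a map that ships as package data and can be
overridden per key from a user YAML file; unknown codes classify as
`unknown` with a logged warning, never silently dropped. Waters count one
per residue. Chlorophyll extraction requires MG, NB and ND; incomplete
residues are excluded and reported.

Deposited component-code vocabularies for the cryptophyte carotenoids
(alloxanthin, crocoxanthin, monadoxanthin, α-carotene) vary between entries,
so the default map carries ALX/CRX/MON/ACR placeholders next to the standard
BCR/ECH/LUT codes; users should check the map against their files.

## Synthetic data: what it emulates, and what it does not

The generator produces the smallest structures that exercise each stage:
chlorophylls as Mg + 4 N coordination frames (downstream geometry uses only
Mg, N_B, N_D), Fe₄S₄ clusters as ideal cubanes, proteins as Cα-only helical
traces, carotenoids/lipids as three-atom placeholders, waters as single O
atoms. `transformed_copy` plants known rigid transforms, per-chain offsets
and seeded Gaussian coordinate noise for parameter-recovery tests.

Two larger builders assemble supercomplex **stand-ins** whose composition
mirrors the published cryptophyte inventories — PSI-ACPI: 255 chl a,
20 chl c, 58+29+12 carotenoids, 44+17+3+1 lipids, 6 detergents, 422 waters,
three Fe–S clusters with exactly 26 waters planted within 8 Å;
PSII-ACPII: 194 chl a, 22 chl c, 676 waters, no Mn₄CaO₅ (the
stationary-phase form lacks the oxygen-evolving complex). Variant builders
derive comparison models with planted differences: a 3.2 Å (or 1.1 Å)
translocation of antenna chain k, extra chlorophylls at exact 17.9 Å and
12.5 Å Mg–Mg distances, ten differently-assigned chlorophyll sites
(5 a→c, 3 c→a, one deletion, one addition), and water sets in which chosen
shell waters survive with sub-match-radius jitter (17 in the
cyanobacteria-like variant, 19 in the plant-like one, union 22).

These stand-ins establish that the pipeline measures planted truth
correctly at realistic problem sizes (~1500 residues, ~275 pigments,
~420 waters, seconds per full run). They do not reproduce real porphyrin
stereochemistry, crystallographic disorder, partial occupancies at pigment
sites, assignment ambiguity near the resolution limit, or lever-arm error
from imperfect core superpositions — so passing tests validate the
computations, not any claim about a particular deposited entry. Analysing
real depositions is a matter of pointing `read_structure` at the files and
supplying the species' chain maps.

## Numerical choices and degenerate inputs

* Dipole undefined when |N_D − N_B| < 0.1 Å (raises, rather than returning a
  garbage direction).
* Coincident Mg positions are an error for distance/κ², not a zero.
* Pair-rule exclusions raise `PairExcludedError` — never a silent zero rate.
* Superposition RMSD is RSSD/√n with unit weights; degenerate selections are
  detected from the singular values of the centered cloud.
* All greedy matchers sort candidates by (distance, site_a, site_b) so ties
  resolve identically on every run and platform.
* Generator determinism: equal specs and seeds produce byte-identical mmCIF.

## Known limitations

* The point-dipole approximation degrades below ~10 Å separation where
  transition densities overlap; rates for the closest pairs are conventional
  figures, not spectroscopic predictions. No spectral-overlap computation,
  exciton delocalization or kinetic propagation is attempted.
* Chl c (and carotenoid) transfer is excluded by default for lack of an
  overlap constant, exactly as in the literature the defaults come from.
* Site matching and water conservation are geometric; they cannot
  distinguish a genuinely absent cofactor from one unmodelled at low local
  resolution.
* Chain correspondence across species is user configuration; the package
  will not guess homology.
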