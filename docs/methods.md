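# Methods

## The elastic-network model

Structures are reduced to one node per residue at the Cα position. Two
nodes interact through an identical harmonic spring when their Euclidean
distance is at most the cutoff `r_c`; the default `r_c = 10 Å` is the
standard choice for Cα-level GNM work and is used everywhere unless
overridden. The Kirchhoff matrix Γ is the graph Laplacian of this contact
network. Residue fluctuations and their couplings follow from the
eigendecomposition of Γ: the raw covariance restricted to a mode subset S
is `Σ_{k∈S} λ_k⁻¹ u_k u_kᵀ`, and over all N−1 nonzero modes this equals
the Moore–Penrose pseudo-inverse of Γ (asserted against a brute-force
pseudo-inverse oracle in the tests).

The physical prefactor `3 k_B T / γ` is set to 1: all GNM fluctuation
quantities are reported in these reduced units. Shapes of MSF profiles
and all normalized correlations are unaffected — the constants cancel in
`C_ij = raw_ij / sqrt(raw_ii raw_jj)` — and no absolute Å² values are
claimed for GNM output. Trajectory-derived MSF, by contrast, is a real
positional variance and is reported in Å².

Numerical conventions:

* eigenvalues below `1e-8 × λ_max` count as zero modes (robust for
  integer-valued Laplacians across the sizes used here); a connected graph
  has exactly one, and extra zero modes mark a disconnected structure,
  which downstream map operations reject by raising;
* eigenvector signs are fixed by making each column's largest-magnitude
  entry positive, so outputs are deterministic; all hinge detection is
  invariant under sign flips anyway;
* the normalized map's diagonal is set to exactly 1 and raw maps are
  symmetrized, removing last-ulp asymmetries from the matrix products;
* "average ten slowest modes" maps are the cumulative λ⁻¹-weighted
  spectral sum over nonzero modes 1–10, normalized once at the end — not
  a mean of ten individually normalized per-mode maps. The cumulative
  convention preserves the spectral weighting of the underlying
  covariance; the mode range is an explicit parameter everywhere, so the
  alternative reading costs one argument to explore. Structures with
  fewer than ten nonzero modes use all of them and record the truncation
  in the mode-range label.

## Hinge detection

Two complementary definitions are implemented. **Minima hinges** scan an
averaged mode shape (mean squared eigenvector entries) for local minima
within a sliding window (default 5 residues, odd) that also lie at or
below a floor quantile of the shape (default 0.25); contiguous qualifying
residues merge into segments, and only interior residues qualify — a
monotone run ending at a terminus is not a hinge. The window and quantile
defaults are package choices: no numeric rule exists in the source
analyses, and both are exposed as parameters. **Crossover hinges** walk
each chain in residue order and report both flanking residues wherever an
individual slow mode changes sign, with exactly-zero entries between
opposite signs assigned to the hinge segment. Crossovers are never
detected across chain boundaries, where sequence adjacency is
meaningless. For a connected network every nonzero mode is orthogonal to
the uniform vector, so a crossover always exists somewhere.

On the synthetic dumbbells used for validation, hinge tests read the
*slowest* mode only (`modes 1:1`). The dumbbells' 3-residue linkers are so
much floppier than real inter-domain hinges that modes 2–3 are localized
linker oscillations with *maxima* at the linker; the domain-versus-domain
mode that defines the designed hinge is always mode 1 (λ₁ ≪ λ₂ by an
order of magnitude). For real structures the averaged three-slowest shape
remains the default in the CLI.

## Ensembles, difference maps, switch score

Ensemble maps average the per-member *normalized* maps, not raw
covariances: members may differ in overall stiffness, and the quantity of
interest is the normalized correlation. Bit-identical members short-cut
to a single evaluation, which also keeps the "ensemble of n identical
copies equals the single map" identity exact in floating point. A
disconnected member aborts the run with its model id.

Difference maps align two states on the intersection of their
`(chain, residue number, insertion code)` keys — author numbering is
authoritative and never rewritten, so region definitions stated in author
numbering carry across states — and subtract normalized values, A − B.
Antisymmetry under state swap and exact zero on identical inputs are
structural and tested.

The switch report computes, per subunit: hinge↔own-DNA-domain,
hinge↔partner-hinge, hinge↔cAMP-site (own and partner),
hinge↔DNA-site (own and partner), and cAMP-site↔DNA-site couplings, each
the mean normalized correlation over the region pair's residue product. A
subunit is **on** iff hinge↔partner-hinge ≥ θ₁ and hinge↔partner-cAMP-site
≥ θ₂, with θ₁ = θ₂ = 0.2 by default. The thresholds quantify a
qualitative distinction, so the report always carries the raw couplings;
conclusions should cite those, not just the labels.

## Trajectory analysis

Superposition is Kabsch (SVD with the determinant sign corrected, so
reflections are never applied), and the self-superposition returns
exactly zero. RMSD series use the first post-equilibration frame as the
fixed reference, matching the convention of measuring drift from the
initial structure; equilibration discard is a frame-count parameter
(default 0, appropriate for synthetic series).

Radius clustering follows the kclust idea: pass 1 seeds a new cluster
whenever a frame lies farther than the radius from every existing
centroid, then reassignment and centroid refinement iterate to a stable
partition; the cluster count is an output of the radius. Distances are
*pairwise* Kabsch RMSDs between a frame and a centroid, and a centroid is
the mean of its members after superposing each onto it. An earlier design
superposed all frames once onto the first frame and used fixed-frame
coordinate RMSDs; that breaks when a distinct conformational state has a
degenerate optimal rotation onto the reference — orientation noise then
splits the state into spurious clusters — which is why the
reference-free metric is used. The radius is honoured approximately, as
in kclust: at convergence members are near, but not guaranteed within,
the radius of their centroid. Best members are the frames of minimum RMSD
to their centroid.

Essential modes come from the SVD of the (T × 3N) matrix of deviations
from the time-mean structure after superposing all frames onto the first;
eigenvalues are variances s²/T, the full nonzero spectrum is kept so the
trace identity with the total Cα variance holds exactly, and a request
beyond the rank truncates with a warning. Essential-mode correlation maps
contract the per-residue 3-vector blocks of the kept eigenvectors,
weighted by variance; with all modes this equals the direct covariance
correlation (tested to 1e-8 against that independent computation).
Per-state maps are normalized before any averaging, consistent with the
ensemble convention.

## Synthetic data: what it emulates, what it does not

The generators produce geometry and contact topology only — no
force-field energetics, no sequence, no solvent:

* **Chains** are smooth self-avoiding random walks with exact 3.8 Å
  consecutive spacing and a 3.4 Å self-avoidance floor, connected at the
  10 Å cutoff.
* **Dumbbells** are two spherical random packings (minimum pair distance
  3.6 Å, ~120 Å³ per residue, giving a protein-like mean contact degree of
  roughly 10–14 at 10 Å) joined by an extended linker whose indices are
  returned as the designed hinge; `inter_domain_contacts` pulls the
  domains together until that many direct cross-domain contacts exist,
  emulating the open→closed transition.
* **Switch dimers** embody the two states of the hinge-mediated switch
  with deterministic lattice-packed domains (cubic lattice at Cα spacing)
  plus small seeded Gaussian jitter (σ = 0.25 Å). The on state packs the
  subunits face-to-face across their cAMP-domain analogs with both
  arched linkers meeting at the interface — one stiff fused core with the
  DNA-domain analogs hanging free — so the hinge co-moves with the
  partner's hinge and cAMP site. The off state joins the subunits at the
  far end of the cAMP domain, remote from the hinge. The lattice core is
  a deliberate design: with random packings the interface geometry (face
  flatness, hinge exposure) varies enough from seed to seed that the
  designed contact architecture often fails to form, defeating the
  purpose of a constructed fixture. The generic `make_dimer` keeps random
  packings and places a C2 copy against any compact surface patch.
* **Perturbed ensembles** add i.i.d. Gaussian noise per coordinate
  (NMR-model stand-ins); **two-state trajectories** hop between two
  conformers with additive noise and record their ground-truth labels and
  separation margin.

Passing tests on these synthetics demonstrates that the machinery is
correct — spectra, maps, detectors, clustering, scoring — under known
ground truth. They do not demonstrate that real apo/holo ensembles
reproduce any particular published correlation pattern: real proteins
have anisotropic packing, sequence-specific contacts and genuinely
flexible interiors that rigid-blob constructs lack. One concrete instance:
in the off-state construct the two subunits rock quasi-rigidly about
their tail interface, so *intra*-subunit couplings are uniformly high and
the off-minus-on difference map is mildly positive in the
cAMP-site × DNA-site block, whereas in CRP itself that coupling weakens
in apo. The difference-map sign test asserts the construction-derived
behavior, not the protein-specific one.

Every generator draws from a single explicitly seeded stream and is
bit-exact reproducible.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| GNM cutoff | 10 | Å | standard Cα contact radius; all calculations |
| GNM mode range | 1:10 | — | slow-mode subset for maps and profiles |
| zero tolerance | 1e-8 (relative) | — | zero-mode classification |
| hinge window / floor quantile | 5 / 0.25 | residues / — | minima detector |
| cluster radius | 3.5 | Å | coarsest published radius; cluster count is an output |
| essential modes kept | 10 | — | leading-PCA subset for maps |
| switch thresholds θ₁, θ₂ | 0.2 / 0.2 | — | on/off labeling; raw couplings always reported |
| equilibration discard | 0 | frames | synthetic default; set ~1250/12500 for 4 ps-sampled dimer/monomer MD |

## Problem sizes

Validation runs at desk scale: random synthetics up to 60 residues for
the spectral oracle, 53-residue dumbbells (20 seeds) for hinge recovery,
40-frame two-state trajectories (10 seeds) for cluster recovery, and
106-residue dimers for the switch score. The full test suite and the
acceptance script each complete in well under a minute.

## Known limitations

* Isotropic GNM only: no anisotropic (3N × 3N) network, no
  distance-weighted springs, no mass weighting.
* Heteroatoms (ligands, nucleic acids) are never network nodes; ligand
  effects enter only through the protein conformation they stabilize.
* Multi-model PDB is the only trajectory format; binary MD formats must
  be converted upstream.
* The kclust-style radius semantics are an interpretation (the original
  tool's exact seeding is unpublished); partitions on well-separated
  states are order-independent, but borderline assignments can depend on
  frame order.
* Region specifications are contiguous author-numbered ranges per chain;
  discontiguous functional sites need multiple named regions.
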