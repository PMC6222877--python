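# Methods

## Model and assumptions

`tunnelflex` treats a protein as a set of van der Waals spheres in the PDB
coordinate frame (Å, no re-centering).  Each residue splits into a static
main chain (N, Cα, C, O) and a side chain that rotates as **one rigid
body** about the Cα–Cβ axis.  This single-axis model is a deliberate
simplification of the full rotamer tree (a long side chain has up to four
rotation axes, three staggered positions each, i.e. 3⁴ = 81 combinations):
the Cα–Cβ axis dominates the volume a side chain can sweep, and a fine
30° grid (12 rotamers) around it stands in for the positions the deeper
axes could reach.  The backbone is rigid throughout; conformations that
would require main-chain motion are out of scope by construction.

A collision is a strict sphere overlap between non-bonded atoms; tangency
is allowed.  Two rotamers of different residues are always non-bonded, so
any atom-pair overlap between them invalidates the pair.

The tunnel is a discretely sampled swept ball: ordered samples
`(t, center, radius)` with `t` strictly increasing in [0, 1].  All
bottleneck reasoning happens on the samples — no interpolation — with the
neighborhood ε of the local-minimum rule equal to one sample step.

## Pipeline

1. **Adjacency** — a residue belongs to the tunnel-adjacent set S iff its
   BSV (one sphere enclosing main chain plus every rotamer) intersects any
   tunnel ball, tangency included.  Because the BSV spans all rotamers this
   covers both residues touching the tunnel in the input pose and residues
   that could only swing into it.
2. **Pruning** — a rotamer is invalid if it collides with any residue's
   main chain (case 1) or with anything outside S: side chains of non-S
   residues and hetero obstacles (case 2).  Neither can happen in a sane
   pose, so such rotamers are dropped (logged at debug level).  A residue
   losing all rotamers is an error: the static environment already
   contradicts the model.
3. **Graphs** — residue-level: TG (edge ⇔ BSV overlap) filtered to CG
   (edge ⇔ at least one rotamer pair actually collides); pairs without a
   TG edge are provably safe and never scanned.  Maximal cliques of CG
   (Bron–Kerbosch with pivoting, via networkx) localize all possible
   conflicts.  Rotamer-level, per clique: FG_k with an edge for every
   *non*-colliding inter-residue rotamer pair; maximal cliques of FG_k
   covering all clique members are the local valid conformations.
4. **Combination** — depth-first merge of local conformations across
   cliques with compatibility pruning (no position may carry two different
   rotamer indices); memory grows with the number of local conformations,
   not their product.  Output is deduplicated and sorted.
5. **Bottlenecks** — per global conformation the tunnel radii are
   re-measured as clearance along the fixed centerline; the maximum of the
   per-conformation minimum bottlenecks is the maximum passable ligand
   radius, reported with a min/mean/max spread.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| rotamer step | 30° | 12 rotamers per residue; configurable (must divide 360°), coarser grids are useful for tests and demonstrations |
| radius table | Bondi-style (C 1.70, N 1.55, O 1.52, S 1.80 Å, …) | feeds the collision rule directly, so it is explicit and swappable (JSON file / `RadiusTable`) |
| collision tolerance | 1e-9 Å² | subtracted from the squared radius sum so floating-point tangency never flips into a collision |
| clearance cap `r_cap` | 2 × max input radius | bounds recomputed radii where the centerline exits the protein, keeping reports comparable across conformations |
| brute-force bound | 10⁶ candidates | guard on the verification oracle only |
| `max_conformations` | unlimited | optional abort threshold for the global enumeration |

## Numerical and semantic choices

- **Tangency** is *not* a collision (strict inequality) but *does* count
  for tunnel adjacency and BSV overlap — the broad phase must be
  conservative, the narrow phase exact.
- **Bottleneck plateaus**: a run of equal minimal radii flanked by strictly
  larger neighbors counts as one bottleneck, reported at the run's first
  sample; profile endpoints are never bottlenecks.  A monotone profile has
  no interior minimum, so the minimum bottleneck falls back to the global
  minimum radius — the narrowest sample still limits what can pass.
- **Conformation vectors** use −1 as the only sentinel; rotamer index 0
  (the input pose) is a real assignment, so the compatibility test is on
  `>= 0`.  Overlapping cliques can reach the same full assignment along
  different branches; the final set is deduplicated, and reported counts
  are counts of distinct assignments.
- **Bonded-pair exclusion**: when a rotamer is tested against its *own*
  main chain, the pairs (Cβ,Cα), (Cβ,N), (Cβ,C) are skipped — Cβ is
  covalently bonded to Cα and sits in forced tetrahedral near-contact with
  N and C in every pose.  Atoms deeper in a real side chain (Cγ onward)
  also sit within van-der-Waals overlap of their own backbone at realistic
  bond lengths, which under this strict rule would prune every rotamer of
  every residue; the `self_main_chain=False` flag
  (`--no-self-mainchain-check`) turns the self-check off entirely for
  structures where that matters.  The synthetic fixtures sidestep the issue
  with reduced radii (below).
- **Enclosing spheres** use a deterministic Ritter-style two-pass
  construction rather than an exact minimal sphere: BSVs are a conservative
  pre-filter, so an oversized bound can only cost time (extra exact pair
  scans), never correctness.
- **Altloc policy**: highest occupancy wins, ties go to the
  lexicographically smallest altloc ('A').  First model only unless
  requested otherwise.  Waters are dropped; non-water HETATM groups are
  static obstacles by default (`include_hetero=False` removes them, for
  structures where a ligand should not block its own exit path).
- **Determinism**: residues, vertices, cliques and conformations are
  always emitted in sorted order; reports key conformations by their row
  index in the sorted global set, with argmax ties resolved to the lowest
  id.

## Tunnel recomputation: a fixed-centerline clearance model

Re-running a full tunnel-finding algorithm per conformation would re-route
the tunnel when a side chain blocks it.  `tunnelflex` instead keeps the
centerline fixed and recomputes each sample radius as the distance from
the sample center to the nearest obstacle surface (static atoms plus the
selected rotamers' side chains), clamped to [0, r_cap].  This preserves
the bottleneck semantics along the same path, is deterministic and
self-contained, and a radius of 0 cleanly encodes "fully blocked".  The
cost is that **entrance relocation cannot occur**: a deformation that
would push the tunnel onto a different path is reported as a narrowing of
the original path instead.  The step is isolated behind
`recompute_tunnel`, so a genuine tunnel finder can be substituted.

## Synthetic fixtures: what they do and do not show

The **worked example** exists twice: as abstract graph relations (three
residues, three rotamers each, two invalid, three colliding pairs) pinning
the expected counts independent of geometry, and as concrete coordinates
(vertical Cα–Cβ axes, one arm atom per residue on a 120° circle, two
planted static glycines) proving the full pipeline realizes those
relations.  The geometric construction validates itself on creation: it
re-runs adjacency and pruning, compares the collision matrix against the
planted relations, and checks that the input tunnel is collision-free
against the input pose.

**Random toys** place n pseudo-residues (four main-chain atoms plus a
2–3-atom arm with a genuine rotation axis, protein-like 1.4–1.5 Å bond
lengths) at lateral offsets from a gently curved centerline.  The
`packing` knob maps to residue spacing: 0 yields pairwise-disjoint BSVs
(every clique a singleton, conformation count = product of surviving
rotamer counts), 1 yields heavy overlap and planted collision structure.
Tunnel radii are drawn and then clamped below the input-pose clearance so
the initial tunnel is collision-free by construction.  Toys use an
all-carbon 0.7 Å radius table: at full Bondi radii any chemically bonded
arm geometry overlaps its own backbone under the strict non-bonded rule
(see the exclusion note above), and the fixtures' purpose is controllable
collision structure, not chemistry.

Consequently, passing tests demonstrate the *combinatorial and geometric
machinery* — exhaustiveness and soundness of the enumeration, the BSV
guarantee, bottleneck semantics — on structures whose collision density
brackets realistic cases.  They do not demonstrate chemical realism of
rotamer populations (no energies, no rotamer libraries, no hydrogens) nor
tunnel re-routing behavior.

## Problem sizes

The bundled verification runs use toys of 3–5 tunnel-adjacent residues
with 12 rotamers each (candidate spaces up to 12⁵ = 248 832, global sets
up to ~10⁵ conformations), 20 seeded repetitions for the oracle-equality
and BSV-soundness checks, and 1000 random radius profiles of length 3–50
for the bottleneck rule.  These sizes keep the brute-force oracle exact
and the full suite fast while exercising every code path; the pipeline
itself scales to far larger sets (enumeration is output-sensitive).

## Known limitations

- Single rotation axis per side chain; no χ₂+ dihedrals, no rotamer
  libraries, no energy ranking — validity is purely geometric.
- Fixed backbone and fixed tunnel centerline; entrance relocation and
  path changes are out of scope.
- Strict vdW spheres with no softening; results are sensitive to the
  radius table, which is why it is explicit and overridable.
- PDB input only (no mmCIF), first model by default, no PDB writing.
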