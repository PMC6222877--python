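"""Exhaustive conformation enumeration on a dense random toy.

Generates a seeded 5-residue toy molecule packed around a curved tunnel,
enumerates every collision-free rotamer assignment with the
divide-and-conquer pipeline, and cross-checks the count against the
brute-force product-space oracle.  The two counts must match exactly —
the pipeline is exhaustive, not approximate.
"""

from tunnelflex.enumeration import brute_force_enumerate
from tunnelflex.fixtures import ToySpec, random_toy
from tunnelflex.pipeline import enumerate_conformations
from tunnelflex.rotamers import candidate_space

spec = ToySpec(n_residues=5, packing=1.0, seed=3, atoms_per_side_chain=3)
molecule, tunnel = random_toy(spec)
result = enumerate_conformations(molecule, tunnel)

n = result.adjacent.n
print(f"toy: {spec.n_residues} residues, packing {spec.packing}, "
      f"seed {spec.seed}")
print(f"tunnel-adjacent residues: {n}")
print(f"candidate space (12^{n}): {candidate_space(n)}")
print(f"amino-collision cliques: "
      f"{[sorted(f'{c}{num}' for c, num, _ in cl.members) for cl in result.cliques]}")
print(f"local conformation counts: {[ls.count for ls in result.local_sets]}")
print(f"global valid conformations: {result.global_conformations.count}")

oracle = brute_force_enumerate(result.adjacent)
match = set(result.global_conformations.conformations) == set(
    oracle.conformations
)
print(f"brute-force oracle count:   {oracle.count}  (sets equal: {match})")
print("-> every rotamer assignment with zero inter-residue atom overlaps, "
      "and only those, is emitted")
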