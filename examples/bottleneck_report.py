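"""Maximum-bottleneck analysis of a flexibly deforming toy tunnel.

For every valid side-chain conformation the tunnel's clearance profile is
re-measured along its centerline and the minimum bottleneck extracted; the
report gives the maximum over conformations (the largest spherical ligand
that can pass under side-chain flexibility) and the min/mean/max spread
(how much the tunnel 'breathes').
"""

from tunnelflex.fixtures import ToySpec, random_toy
from tunnelflex.pipeline import max_bottleneck_analysis
from tunnelflex.tunnel import find_bottlenecks

spec = ToySpec(n_residues=3, packing=0.9, seed=2, tunnel_samples=12)
molecule, tunnel = random_toy(spec)
result, report = max_bottleneck_analysis(molecule, tunnel)

print(f"input tunnel: {len(tunnel)} samples, radii "
      f"{[round(float(r), 2) for r in tunnel.radii]}")
print(f"input bottlenecks at samples "
      f"{[b.sample_index for b in find_bottlenecks(tunnel)]}")
print(f"valid conformations analyzed: {result.global_conformations.count}")
lo, mean, hi = report.summary
print(f"bottleneck spread over conformations: "
      f"min {lo:.3f}, mean {mean:.3f}, max {hi:.3f} Å")
print(f"maximum bottleneck: {report.max_bottleneck:.3f} Å "
      f"(conformation id {report.argmax_conformation})")
print("-> min is the worst-case passable ligand radius, max the best case; "
      "0 would mean some conformation blocks the tunnel entirely")
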