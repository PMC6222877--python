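"""Maximum bottleneck of the flexibly deformed tunnel.

For every global valid conformation the tunnel is re-measured (clearance
along the fixed centerline), its minimum bottleneck extracted, and the
maximum of those minima reported: the largest spherical ligand that can
pass through the tunnel under some valid side-chain arrangement.  The
min/mean/max summary over conformations describes how much the bottleneck
breathes as side chains rotate; a value of 0 means some conformation blocks
the tunnel completely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .enumeration import GlobalConformationSet
from .model_io import Molecule
from .rotamers import AdjacentSet
from .tunnel import TunnelProfile, min_bottleneck_radius, recompute_tunnel


@dataclass(frozen=True)
class BottleneckReport:
    """Per-conformation minimum bottlenecks and their maximum.

    Conformation ids are row indices into the sorted global conformation
    set, so reports are stable across runs; argmax ties resolve to the
    lowest id.
    """

    per_conformation: dict
    max_bottleneck: float
    argmax_conformation: int
    summary: tuple[float, float, float]  # (min, mean, max)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_conformation": {
                str(k): v for k, v in self.per_conformation.items()
            },
            "max_bottleneck": self.max_bottleneck,
            "argmax_conformation": self.argmax_conformation,
            "summary": {
                "min": self.summary[0],
                "mean": self.summary[1],
                "max": self.summary[2],
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def analyze(
    tunnel: TunnelProfile,
    globals_: GlobalConformationSet,
    adjacent: AdjacentSet,
    molecule: Molecule,
    r_cap: float | None = None,
) -> BottleneckReport:
    """Bottleneck analysis over every global valid conformation."""
    if globals_.count == 0:
        raise ValueError("no global conformations to analyze")
    per: dict[int, float] = {}
    for cid, conf in enumerate(globals_.conformations):
        deformed = recompute_tunnel(tunnel, conf, adjacent, molecule, r_cap=r_cap)
        per[cid] = min_bottleneck_radius(deformed)
    best = max(per.values())
    argmax = min(cid for cid, v in per.items() if v == best)
    vals = list(per.values())
    summary = (min(vals), sum(vals) / len(vals), max(vals))
    return BottleneckReport(
        per_conformation=per,
        max_bottleneck=best,
        argmax_conformation=argmax,
        summary=summary,
    )
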