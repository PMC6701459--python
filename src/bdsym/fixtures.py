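"""Deterministic test fixtures: tiny Newick trees and parameter grids.

``generate_fixtures`` writes hand-constructed trees with documented
branching times, small batches of simulated conditioned trees, and the
parameter grid used by the symmetry checks, together with a manifest of
SHA-256 hashes so bit-reproducibility across runs is checkable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .params import BDParams
from .simulator import SimConfig, simulate_reconstructed_tree
from .tree_densities import Conditioning, write_newick

__all__ = ["HAND_TREES", "generate_fixtures"]

# hand-constructed ultrametric trees; branching times (ages) in comments
HAND_TREES = {
    "hand_n1.nwk": "A:1.5;",                                    # stem age 1.5
    "hand_n2.nwk": "(A:1,B:1):0.5;",                            # t1=1, stem 1.5
    "hand_n3.nwk": "((A:1,B:1):1,C:2);",                        # t=(2,1)
    "hand_n4.nwk": "(((A:0.5,B:0.5):1,C:1.5):1,D:2.5);",        # t=(2.5,1.5,0.5)
    "hand_n5.nwk": "((((A:0.4,B:0.4):0.6,C:1):1,D:2):1,E:3);",  # t=(3,2,1,0.4)
}

_SIM_CONDITIONINGS = (
    Conditioning.STEM_SURVIVAL,
    Conditioning.CROWN_SURVIVAL,
    Conditioning.STEM_AND_N,
    Conditioning.CROWN_AND_N,
)
_SIM_PARAMS = BDParams(1.0, 0.5, 0.8)
_SIM_DURATION = 3.0
_SIM_N_TIPS = 4
_TREES_PER_CONDITIONING = 50


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixtures(out_dir, seed: int, trees_per_conditioning: int = _TREES_PER_CONDITIONING):
    """Write the fixture set into ``out_dir``; returns {filename: sha256}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    for name, newick in HAND_TREES.items():
        path = out / name
        path.write_text(newick + "\n")
        manifest[name] = _sha256(path)

    for k, cond in enumerate(_SIM_CONDITIONINGS):
        lines = []
        for rep in range(trees_per_conditioning):
            config = SimConfig(
                params=_SIM_PARAMS,
                conditioning=cond,
                duration=_SIM_DURATION,
                n_tips=_SIM_N_TIPS if "and_n" in cond.value else None,
                seed=seed + 1000 * k + rep,
            )
            result = simulate_reconstructed_tree(config)
            lines.append(write_newick(result.tree, seed=seed))
        name = f"sim_{cond.value}.nwk"
        path = out / name
        path.write_text("\n".join(lines) + "\n")
        manifest[name] = _sha256(path)

    grid = pd.DataFrame(
        [
            (lam, mu, t)
            for lam in (0.3, 1.0, 2.5)
            for mu in (0.3, 1.0, 2.5)
            for t in (0.1, 0.5, 1.0, 2.0)
        ],
        columns=["birth_rate", "death_rate", "t"],
    )
    grid_path = out / "symmetry_grid.csv"
    grid.to_csv(grid_path, index=False)
    manifest["symmetry_grid.csv"] = _sha256(grid_path)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
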