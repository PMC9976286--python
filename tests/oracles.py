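"""Independent brute-force oracles used to cross-check the fast paths."""
from __future__ import annotations

import itertools

import numpy as np

from phore.geometry import apply_rigid, superpose


def brute_force_match(model, ligand_features):
    """Exhaustive correspondence search over all injective kind-compatible
    mappings; returns the best fit score or None when nothing matches.

    Shares only the superposition primitive with the production matcher —
    the search itself is plain enumeration.
    """
    n = model.n_features
    mcent = model.feature_centers()
    lcent = np.array([f.center for f in ligand_features], dtype=float)
    tol = np.array([f.tolerance for f in model.features])
    choices = [[j for j, lf in enumerate(ligand_features) if lf.kind == mf.kind]
               for mf in model.features]
    best = None
    for combo in itertools.product(*choices):
        if len(set(combo)) != n:
            continue
        R, t = superpose(lcent[list(combo)], mcent)
        d = np.linalg.norm(apply_rigid(lcent[list(combo)], R, t) - mcent,
                           axis=1)
        if np.any(d > tol + 1e-9):
            continue
        score = float(np.sum(1.0 - d / tol))
        if best is None or score > best:
            best = score
    return best
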