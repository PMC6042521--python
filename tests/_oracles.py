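"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the
equivalence-class likelihood maximizer here is a plain grid search with
iterative refinement, not EM.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np


def _compositions(total: int, parts: int) -> np.ndarray:
    """All integer vectors of length `parts` summing to `total`."""
    out = []
    for cuts in combinations_with_replacement(range(total + 1), parts - 1):
        prev = 0
        vec = []
        for c in cuts:
            vec.append(c - prev)
            prev = c
        vec.append(total - prev)
        out.append(vec)
    return np.array(out, dtype=float)


def class_log_likelihood(theta: np.ndarray, classes, eff: np.ndarray, tid_pos) -> np.ndarray:
    """log prod_c (sum_{t in c} theta_t / l_t)^{n_c} for a batch of thetas."""
    theta = np.atleast_2d(theta)
    ll = np.zeros(theta.shape[0])
    for members, n in classes.items():
        idx = [tid_pos[t] for t in members]
        s = (theta[:, idx] / eff[idx]).sum(axis=1)
        with np.errstate(divide="ignore"):
            ll += n * np.log(s)
    return ll


def grid_mle_theta(classes, effective_lengths: dict, coarse: int = 20, rounds: int = 10):
    """Grid-search maximizer of the equivalence-class likelihood.

    Starts from a simplex lattice of granularity ``coarse`` and refines by
    repeatedly evaluating a shrinking perturbation grid around the incumbent
    (renormalized onto the simplex). Final precision ~1e-5 per coordinate.
    """
    tids = sorted(effective_lengths)
    tid_pos = {t: i for i, t in enumerate(tids)}
    eff = np.array([effective_lengths[t] for t in tids], dtype=float)
    T = len(tids)

    grid = _compositions(coarse, T) / coarse
    ll = class_log_likelihood(grid, classes, eff, tid_pos)
    best = grid[np.argmax(ll)]
    h = 1.0 / coarse
    steps = np.array(np.meshgrid(*[[-1.0, -0.5, 0.0, 0.5, 1.0]] * T)).reshape(T, -1).T
    for _ in range(rounds):
        cand = best + h * steps
        cand = np.clip(cand, 0.0, None)
        sums = cand.sum(axis=1)
        cand = cand[sums > 0] / sums[sums > 0, None]
        ll = class_log_likelihood(cand, classes, eff, tid_pos)
        best = cand[np.argmax(ll)]
        h /= 2.5
    return {t: best[tid_pos[t]] for t in tids}
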