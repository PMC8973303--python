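"""Independent brute-force oracles used only by the test suite."""

from itertools import permutations

import numpy as np


def ks_d_bruteforce(a, b):
    """KS D by exhaustively scanning |ECDF_a - ECDF_b| at every sample point."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    points = np.concatenate([a, b])
    d = 0.0
    for x in points:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        d = max(d, abs(fa - fb))
    return d


def _best_partial_matching(prev_xy, cur_xy, gate):
    """Exhaustive minimum-cost partial matching between two point sets.

    Cost = sum of matched distances + gate*1.0001 per unmatched point on
    either side (mirroring the padded-assignment objective), with matches
    allowed only within the gate.
    """
    n, m = len(prev_xy), len(cur_xy)
    nomatch = gate * 1.0001
    best = (np.inf, {})
    cols = list(range(m)) + [None] * n   # None = unmatched
    seen = set()
    for perm in permutations(cols, n):
        if perm in seen:
            continue
        seen.add(perm)
        used = [c for c in perm if c is not None]
        if len(used) != len(set(used)):
            continue
        cost = 0.0
        ok = True
        for r, c in enumerate(perm):
            if c is None:
                cost += nomatch
            else:
                dist = float(np.linalg.norm(prev_xy[r] - cur_xy[c]))
                if dist > gate:
                    ok = False
                    break
                cost += dist
        if not ok:
            continue
        cost += nomatch * (m - len(used))
        if cost < best[0] - 1e-12:
            best = (cost, {r: c for r, c in enumerate(perm) if c is not None})
    return best[1]


def link_bruteforce(per_frame_xy, gate):
    """Sequential frame-by-frame linking with exhaustive assignment.

    No gap closing (a track missing one frame is retired).  Returns the
    track partition as a set of tuples of (frame, x, y) triples.
    """
    active, finished = [], []
    for t, xy in enumerate(per_frame_xy):
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        still = []
        for tr in active:
            if t - tr["last"] > 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        prev = np.array([tr["pts"][-1][1:] for tr in active]).reshape(-1, 2)
        match = _best_partial_matching(prev, xy, gate) if len(active) else {}
        matched_cols = set(match.values())
        for r, c in match.items():
            active[r]["pts"].append((t, xy[c, 0], xy[c, 1]))
            active[r]["last"] = t
        for c in range(len(xy)):
            if c not in matched_cols:
                active.append({"pts": [(t, xy[c, 0], xy[c, 1])], "last": t})
    finished.extend(active)
    return {tuple(tr["pts"]) for tr in finished}


def grid_search_4pl_rss(logc, y, logec50_grid, hill_grid):
    """Best 4PL residual SS over a (logEC50, hill) grid.

    For each grid point the model is linear in (bottom, top), so they are
    profiled exactly by linear least squares.
    """
    best = np.inf
    for le in logec50_grid:
        for h in hill_grid:
            f = 1.0 / (1.0 + 10.0 ** ((le - logc) * h))
            X = np.column_stack([1.0 - f, f])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((X @ coef - y) ** 2))
            best = min(best, rss)
    return best
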