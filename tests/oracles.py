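"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, enumeration) and
shares no code with the package implementations it checks.
"""

import math

import numpy as np

# D8 neighbour order must match the package's documented precedence.
OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def brute_force_directions(z: np.ndarray, cell: float) -> np.ndarray:
    """Steepest-descent D8 direction per cell; -1 = off-grid outlet."""
    nr, nc = z.shape
    out = np.full((nr, nc), -5, dtype=int)
    for r in range(nr):
        for c in range(nc):
            best, best_k = 0.0, None
            off_grid = False
            for k, (dr, dc) in enumerate(OFFSETS):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc):
                    off_grid = True
                    continue
                dist = cell * (math.sqrt(2.0) if dr and dc else 1.0)
                s = (z[r, c] - z[rr, cc]) / dist
                if s > best:
                    best, best_k = s, k
            if best_k is not None:
                out[r, c] = best_k
            elif off_grid:
                out[r, c] = -1
    return out


def check_directions(direction: np.ndarray, z: np.ndarray, cell: float) -> None:
    """Assert directions equal strict steepest descent; flats (no strict
    descent, undefined under the brute-force rule) must point to an
    equal-elevation neighbour."""
    expected = brute_force_directions(z, cell)
    nr, nc = z.shape
    for r in range(nr):
        for c in range(nc):
            if expected[r, c] != -5:
                assert direction[r, c] == expected[r, c], (r, c)
            else:
                d = direction[r, c]
                assert d >= 0, (r, c)
                dr, dc = OFFSETS[d]
                assert z[r + dr, c + dc] == z[r, c], (r, c)


def brute_force_accumulation(directions: np.ndarray) -> np.ndarray:
    """For every cell, enumerate all cells whose path passes through it."""
    nr, nc = directions.shape
    acc = np.zeros((nr, nc), dtype=int)
    for r0 in range(nr):
        for c0 in range(nc):
            r, c = r0, c0
            seen = set()
            while True:
                acc[r, c] += 1
                seen.add((r, c))
                d = directions[r, c]
                if d < 0:
                    break
                dr, dc = OFFSETS[d]
                r, c = r + dr, c + dc
                if not (0 <= r < nr and 0 <= c < nc):
                    break
                assert (r, c) not in seen, "cycle in directions"
    return acc


def has_pit(z: np.ndarray) -> bool:
    """Any interior cell strictly below all 8 neighbours."""
    nr, nc = z.shape
    for r in range(1, nr - 1):
        for c in range(1, nc - 1):
            if all(z[r + dr, c + dc] > z[r, c] for dr, dc in OFFSETS):
                return True
    return False


def bioclim_oracle(tmin, tmax, prcp):
    """All 19 bioclimatic variables by direct enumeration of the 12 windows."""
    tmin, tmax, prcp = list(tmin), list(tmax), list(prcp)
    tmean = [(a + b) / 2.0 for a, b in zip(tmin, tmax)]

    def pop_sd(xs):
        m = sum(xs) / len(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))

    windows = [[(w + i) % 12 for i in range(3)] for w in range(12)]
    qt = [sum(tmean[i] for i in w) / 3.0 for w in windows]
    qp = [sum(prcp[i] for i in w) for w in windows]

    def argbest(vals, best):
        target = best(vals)
        for i, v in enumerate(vals):
            if v == target:
                return i  # earliest window wins ties

    wet, dry = argbest(qp, max), argbest(qp, min)
    warm, cold = argbest(qt, max), argbest(qt, min)

    out = {}
    out["bio1"] = sum(tmean) / 12.0
    out["bio2"] = sum(b - a for a, b in zip(tmin, tmax)) / 12.0
    out["bio4"] = pop_sd(tmean) * 100.0
    out["bio5"] = max(tmax)
    out["bio6"] = min(tmin)
    out["bio7"] = out["bio5"] - out["bio6"]
    out["bio3"] = out["bio2"] / out["bio7"] * 100.0 if out["bio7"] else 0.0
    out["bio8"] = qt[wet]
    out["bio9"] = qt[dry]
    out["bio10"] = qt[warm]
    out["bio11"] = qt[cold]
    out["bio12"] = sum(prcp)
    out["bio13"] = max(prcp)
    out["bio14"] = min(prcp)
    out["bio15"] = 100.0 * pop_sd(prcp) / (1.0 + out["bio12"] / 12.0)
    out["bio16"] = qp[wet]
    out["bio17"] = qp[dry]
    out["bio18"] = qp[warm]
    out["bio19"] = qp[cold]
    return out


def auc_by_enumeration(pres, bg) -> float:
    wins = 0.0
    for p in pres:
        for b in bg:
            if p > b:
                wins += 1.0
            elif p == b:
                wins += 0.5
    return wins / (len(pres) * len(bg))


def select_best_oracle(rows, e_percent):
    """Brute-force application of the three selection rules.

    rows: list of dicts with p_value, omission, aicc, beta, classes.
    """
    pool = [r for r in rows if r.get("valid", True)]
    sig = [r for r in pool if r["p_value"] < 0.05]
    if sig:
        pool = sig
    low = [r for r in pool if r["omission"] <= e_percent / 100.0]
    if low:
        pool = low
    finite = [r for r in pool if np.isfinite(r["aicc"])]
    if finite:
        pool = finite
    return sorted(pool, key=lambda r: (r["aicc"], r["beta"], len(r["classes"])))[0]
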