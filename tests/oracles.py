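"""Independent brute-force oracles used by the test suite.

Everything here is written as plain Python loops over pixels, dicts and the
defining formulas — deliberately sharing no code with the package — so that
agreement between the two is meaningful evidence of correctness.
"""

from __future__ import annotations

import math

import numpy as np

ANGLES = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def _log2(x: float) -> float:
    return math.log(x, 2)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(levels, mask, offset):
    counts: dict[tuple[int, int], int] = {}
    rows, cols = levels.shape
    dr, dc = offset
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < rows and 0 <= c2 < cols):
                continue
            if mask[r, c] and mask[r2, c2]:
                a, b = int(levels[r, c]), int(levels[r2, c2])
                counts[(a, b)] = counts.get((a, b), 0) + 1
                counts[(b, a)] = counts.get((b, a), 0) + 1
    return counts


def glcm_features(levels, mask, ng):
    acc: dict[str, float] = {}
    for offset in ANGLES:
        counts = glcm_matrix(levels, mask, offset)
        total = sum(counts.values())
        p = {ij: v / total for ij, v in counts.items()}
        feats = _glcm_single(p, ng)
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v / len(ANGLES)
    return acc


def _glcm_single(p, ng):
    px = [0.0] * (ng + 1)
    for (i, j), v in p.items():
        px[i] += v
    mu = sum(v * i for (i, j), v in p.items())
    sigma2 = sum(v * (i - mu) ** 2 for (i, j), v in p.items())
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng + 1)
    for (i, j), v in p.items():
        p_diff[abs(i - j)] += v
        p_sum[i + j] += v
    da = sum(k * v for k, v in enumerate(p_diff))
    hxy = -sum(v * _log2(v) for v in p.values() if v > 0)
    hx = -sum(v * _log2(v) for v in px if v > 0)
    hxy1 = -sum(v * _log2(px[i] * px[j]) for (i, j), v in p.items() if px[i] * px[j] > 0)
    hxy2 = -sum(
        px[i] * px[j] * _log2(px[i] * px[j])
        for i in range(1, ng + 1)
        for j in range(1, ng + 1)
        if px[i] * px[j] > 0
    )
    present = [i for i in range(1, ng + 1) if px[i] > 0]
    if len(present) > 1:
        q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(
                    p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * px[k])
                    for k in present
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 1.0
    out = {
        "Autocorrelation": sum(v * i * j for (i, j), v in p.items()),
        "ClusterProminence": sum(v * (i + j - 2 * mu) ** 4 for (i, j), v in p.items()),
        "ClusterShade": sum(v * (i + j - 2 * mu) ** 3 for (i, j), v in p.items()),
        "ClusterTendency": sum(v * (i + j - 2 * mu) ** 2 for (i, j), v in p.items()),
        "Contrast": sum(v * (i - j) ** 2 for (i, j), v in p.items()),
        "Correlation": (
            (sum(v * i * j for (i, j), v in p.items()) - mu * mu) / sigma2
            if sigma2 > 0
            else 1.0
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * _log2(v) for v in p_diff if v > 0),
        "DifferenceVariance": sum(v * (k - da) ** 2 for k, v in enumerate(p_diff)),
        "Id": sum(v / (1 + abs(i - j)) for (i, j), v in p.items()),
        "Idm": sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items()),
        "Idmn": sum(v / (1 + ((i - j) / ng) ** 2) for (i, j), v in p.items()),
        "Idn": sum(v / (1 + abs(i - j) / ng) for (i, j), v in p.items()),
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
        "InverseVariance": sum(v / (i - j) ** 2 for (i, j), v in p.items() if i != j),
        "JointAverage": mu,
        "JointEnergy": sum(v * v for v in p.values()),
        "JointEntropy": hxy,
        "MaximumProbability": max(p.values()),
        "Mcc": mcc,
        "SumEntropy": -sum(v * _log2(v) for v in p_sum if v > 0),
        "SumSquares": sigma2,
    }
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_runs(levels, mask, offset):
    """All maximal runs along ``offset`` as (level, length) pairs."""
    rows, cols = levels.shape
    dr, dc = offset
    runs = []
    seen = set()
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or (r, c) in seen:
                continue
            # walk back to the start of this run
            r0, c0 = r, c
            while (
                0 <= r0 - dr < rows and 0 <= c0 - dc < cols
                and mask[r0 - dr, c0 - dc]
                and levels[r0 - dr, c0 - dc] == levels[r, c]
            ):
                r0, c0 = r0 - dr, c0 - dc
            if (r0, c0) in seen:
                continue
            length = 0
            rr, cc = r0, c0
            while (
                0 <= rr < rows and 0 <= cc < cols
                and mask[rr, cc] and levels[rr, cc] == levels[r0, c0]
            ):
                seen.add((rr, cc))
                length += 1
                rr, cc = rr + dr, cc + dc
            runs.append((int(levels[r0, c0]), length))
    return runs


def _rl_features(entries, n_pixels, names):
    nr = sum(cnt for (_, _), cnt in entries.items()) if isinstance(entries, dict) else None
    counts = entries
    nr = sum(counts.values())
    p = {k: v / nr for k, v in counts.items()}
    mu_i = sum(v * i for (i, j), v in p.items())
    mu_j = sum(v * j for (i, j), v in p.items())
    row_tot: dict[int, float] = {}
    col_tot: dict[int, float] = {}
    for (i, j), v in counts.items():
        row_tot[i] = row_tot.get(i, 0) + v
        col_tot[j] = col_tot.get(j, 0) + v
    generic = {
        "short": sum(v / j**2 for (i, j), v in counts.items()) / nr,
        "long": sum(v * j**2 for (i, j), v in counts.items()) / nr,
        "gln": sum(v**2 for v in row_tot.values()) / nr,
        "glnn": sum(v**2 for v in row_tot.values()) / nr**2,
        "rln": sum(v**2 for v in col_tot.values()) / nr,
        "rlnn": sum(v**2 for v in col_tot.values()) / nr**2,
        "pct": nr / n_pixels,
        "glv": sum(v * (i - mu_i) ** 2 for (i, j), v in p.items()),
        "rv": sum(v * (j - mu_j) ** 2 for (i, j), v in p.items()),
        "entropy": -sum(v * _log2(v) for v in p.values() if v > 0),
        "lgl": sum(v / i**2 for (i, j), v in counts.items()) / nr,
        "hgl": sum(v * i**2 for (i, j), v in counts.items()) / nr,
        "srlgl": sum(v / (i**2 * j**2) for (i, j), v in counts.items()) / nr,
        "srhgl": sum(v * i**2 / j**2 for (i, j), v in counts.items()) / nr,
        "lrlgl": sum(v * j**2 / i**2 for (i, j), v in counts.items()) / nr,
        "lrhgl": sum(v * i**2 * j**2 for (i, j), v in counts.items()) / nr,
    }
    return {name: generic[key] for key, name in names.items()}


GLRLM_NAMES = {
    "short": "ShortRunEmphasis", "long": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "rln": "RunLengthNonUniformity", "rlnn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage", "glv": "GrayLevelVariance", "rv": "RunVariance",
    "entropy": "RunEntropy", "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis", "srlgl": "ShortRunLowGrayLevelEmphasis",
    "srhgl": "ShortRunHighGrayLevelEmphasis", "lrlgl": "LongRunLowGrayLevelEmphasis",
    "lrhgl": "LongRunHighGrayLevelEmphasis",
}

GLSZM_NAMES = {
    "short": "SmallAreaEmphasis", "long": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "rln": "SizeZoneNonUniformity", "rlnn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage", "glv": "GrayLevelVariance", "rv": "ZoneVariance",
    "entropy": "ZoneEntropy", "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis", "srlgl": "SmallAreaLowGrayLevelEmphasis",
    "srhgl": "SmallAreaHighGrayLevelEmphasis", "lrlgl": "LargeAreaLowGrayLevelEmphasis",
    "lrhgl": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(levels, mask, ng):
    n_pixels = int(np.sum(mask))
    acc: dict[str, float] = {}
    for offset in ANGLES:
        counts: dict[tuple[int, int], int] = {}
        for lv, length in glrlm_runs(levels, mask, offset):
            counts[(lv, length)] = counts.get((lv, length), 0) + 1
        feats = _rl_features(counts, n_pixels, GLRLM_NAMES)
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v / len(ANGLES)
    return acc


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_zones(levels, mask):
    """8-connected same-level zones as (level, size) pairs (flood fill)."""
    rows, cols = levels.shape
    seen = set()
    zones = []
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or (r, c) in seen:
                continue
            lv = int(levels[r, c])
            stack = [(r, c)]
            seen.add((r, c))
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (
                            0 <= r2 < rows and 0 <= c2 < cols
                            and (r2, c2) not in seen
                            and mask[r2, c2] and int(levels[r2, c2]) == lv
                        ):
                            seen.add((r2, c2))
                            stack.append((r2, c2))
            zones.append((lv, size))
    return zones


def glszm_features(levels, mask, ng):
    counts: dict[tuple[int, int], int] = {}
    for lv, size in glszm_zones(levels, mask):
        counts[(lv, size)] = counts.get((lv, size), 0) + 1
    return _rl_features(counts, int(np.sum(mask)), GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_features(levels, mask, ng, alpha=0):
    rows, cols = levels.shape
    counts: dict[tuple[int, int], int] = {}
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            dep = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if (
                        0 <= r2 < rows and 0 <= c2 < cols and mask[r2, c2]
                        and abs(int(levels[r2, c2]) - int(levels[r, c])) <= alpha
                    ):
                        dep += 1
            key = (int(levels[r, c]), dep + 1)  # dependence size incl. center
            counts[key] = counts.get(key, 0) + 1
    nz = sum(counts.values())
    p = {k: v / nz for k, v in counts.items()}
    mu_i = sum(v * i for (i, j), v in p.items())
    mu_j = sum(v * j for (i, j), v in p.items())
    row_tot: dict[int, float] = {}
    col_tot: dict[int, float] = {}
    for (i, j), v in counts.items():
        row_tot[i] = row_tot.get(i, 0) + v
        col_tot[j] = col_tot.get(j, 0) + v
    return {
        "SmallDependenceEmphasis": sum(v / j**2 for (i, j), v in counts.items()) / nz,
        "LargeDependenceEmphasis": sum(v * j**2 for (i, j), v in counts.items()) / nz,
        "GrayLevelNonUniformity": sum(v**2 for v in row_tot.values()) / nz,
        "DependenceNonUniformity": sum(v**2 for v in col_tot.values()) / nz,
        "DependenceNonUniformityNormalized": sum(v**2 for v in col_tot.values()) / nz**2,
        "GrayLevelVariance": sum(v * (i - mu_i) ** 2 for (i, j), v in p.items()),
        "DependenceVariance": sum(v * (j - mu_j) ** 2 for (i, j), v in p.items()),
        "DependenceEntropy": -sum(v * _log2(v) for v in p.values() if v > 0),
        "LowGrayLevelEmphasis": sum(v / i**2 for (i, j), v in counts.items()) / nz,
        "HighGrayLevelEmphasis": sum(v * i**2 for (i, j), v in counts.items()) / nz,
        "SmallDependenceLowGrayLevelEmphasis": sum(
            v / (i**2 * j**2) for (i, j), v in counts.items()) / nz,
        "SmallDependenceHighGrayLevelEmphasis": sum(
            v * i**2 / j**2 for (i, j), v in counts.items()) / nz,
        "LargeDependenceLowGrayLevelEmphasis": sum(
            v * j**2 / i**2 for (i, j), v in counts.items()) / nz,
        "LargeDependenceHighGrayLevelEmphasis": sum(
            v * i**2 * j**2 for (i, j), v in counts.items()) / nz,
    }


# ---------------------------------------------------------------------------
# First order
# ---------------------------------------------------------------------------

def _percentile(sorted_x, q):
    """Linear-interpolation percentile (rank = (n-1) * q/100)."""
    n = len(sorted_x)
    rank = (n - 1) * q / 100.0
    lo = int(math.floor(rank))
    hi = int(math.ceil(rank))
    frac = rank - lo
    return sorted_x[lo] * (1 - frac) + sorted_x[hi] * frac


def firstorder_features(image, levels, mask, ng):
    x = sorted(float(image[r, c]) for r, c in zip(*np.where(mask)))
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    p10, p25, p75, p90 = (_percentile(x, q) for q in (10, 25, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    hist: dict[int, int] = {}
    for r, c in zip(*np.where(mask)):
        lv = int(levels[r, c])
        hist[lv] = hist.get(lv, 0) + 1
    probs = [v / n for v in hist.values()]
    if var > 0:
        skew = (sum((v - mean) ** 3 for v in x) / n) / var**1.5
        kurt = (sum((v - mean) ** 4 for v in x) / n) / var**2
    else:
        skew = kurt = 0.0
    if n % 2:
        median = x[n // 2]
    else:
        median = (x[n // 2 - 1] + x[n // 2]) / 2
    energy = sum(v * v for v in x)
    return {
        "Energy": energy,
        "TotalEnergy": energy,
        "Entropy": -sum(p * _log2(p) for p in probs if p > 0),
        "Minimum": x[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": median,
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": sum(p * p for p in probs),
    }


# ---------------------------------------------------------------------------
# ICC and AUC
# ---------------------------------------------------------------------------

def icc_2_1_anova(ratings):
    """ICC(2,1) by explicit sums of squares."""
    x = [[float(v) for v in row] for row in ratings]
    n = len(x)
    k = len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if sst == 0:
        return 1.0
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def auc_concordance(truth, scores):
    """AUC as the pairwise concordance probability (ties count 1/2)."""
    pos = [s for t, s in zip(truth, scores) if t]
    neg = [s for t, s in zip(truth, scores) if not t]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
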