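"""Independent brute-force reference implementations of every measure.

These operate on plain point sets with explicit minimum-over-points Euclidean
distances — no distance transform, no shared code with the package — and serve
as the oracle the fast implementations are checked against on small grids.
"""

import math


def min_dist(p, points):
    """Minimum Euclidean distance from pixel p to a point set (inf if empty)."""
    if not points:
        return math.inf
    return min(math.hypot(p[0] - q[0], p[1] - q[1]) for q in points)


def confusion(gt, dc, shape):
    tp = len(gt & dc)
    fp = len(dc - gt)
    fn = len(gt - dc)
    tn = shape[0] * shape[1] - tp - fp - fn
    return tp, fp, fn, tn


def delta_max(gt, shape):
    """Max over every grid pixel of its distance to the ground-truth set."""
    return max(min_dist((r, c), gt)
               for r in range(shape[0]) for c in range(shape[1]))


def dice(gt, dc, shape):
    tp, fp, fn, _ = confusion(gt, dc, shape)
    return 2.0 * tp / (2.0 * tp + fn + fp)


def fom(gt, dc, shape, kappa=1.0 / 9.0):
    denom = max(len(gt), len(dc))
    return sum(1.0 / (1.0 + kappa * min_dist(p, gt) ** 2) for p in dc) / denom


def f_measure(gt, dc, shape, kappa=1.0 / 9.0, beta=1.0):
    _, fp, _, _ = confusion(gt, dc, shape)
    total = 0.0
    for p in gt:
        d = min_dist(p, dc)
        total += 0.0 if math.isinf(d) else 1.0 / (1.0 + kappa * d**2)
    return total / (len(gt) + beta * fp)


def d4(gt, dc, shape, kappa=1.0 / 9.0):
    tp, fp, fn, _ = confusion(gt, dc, shape)
    mx = max(len(gt), len(dc))
    stat = ((tp - mx) ** 2 + fn**2 + fp**2) / mx**2
    return 1.0 - 0.5 * math.sqrt(stat + (1.0 - fom(gt, dc, shape, kappa)) ** 2)


def dp(gt, dc, shape, kappa=1.0 / 9.0):
    n_pix = shape[0] * shape[1]
    fp_pts = dc - gt
    fn_pts = gt - dc
    tp_pts = gt & dc
    fp_term = sum(1.0 - 1.0 / (1.0 + kappa * min_dist(p, gt) ** 2) for p in fp_pts)
    fp_term /= 2.0 * (n_pix - len(gt))
    fn_term = 0.0
    for p in fn_pts:
        d = min_dist(p, tp_pts)
        fn_term += 1.0 if math.isinf(d) else 1.0 - 1.0 / (1.0 + kappa * d**2)
    fn_term /= 2.0 * len(gt)
    return 1.0 - fp_term - fn_term


def emm(gt, dc, shape, mdist=None, dmax=None, omega=None, epsilon=2.0):
    n_pix = shape[0] * shape[1]
    mdist = n_pix / 40.0 if mdist is None else mdist
    dmax = n_pix / 10.0 if dmax is None else dmax
    omega = 10.0 / n_pix if omega is None else omega
    tp = len(gt & dc)
    if tp == 0:
        return 0.0

    def thresh(d):
        return d if d < mdist else dmax

    fn_sum = sum(thresh(min_dist(p, dc)) for p in gt - dc)
    fp_sum = sum(thresh(min_dist(p, gt)) for p in dc - gt)
    return tp / (tp + omega * (fn_sum + epsilon * fp_sum))


def rde(gt, dc, shape, k=2, root=True):
    mean_dc = sum(min_dist(p, gt) ** k for p in dc) / len(dc)
    mean_gt = sum(min_dist(p, dc) ** k for p in gt) / len(gt)
    if root:
        return mean_dc ** (1.0 / k) + mean_gt ** (1.0 / k)
    return mean_dc + mean_gt


def m_measure(gt, dc, shape, mu_fp, mu_fn):
    tp, fp, fn, _ = confusion(gt, dc, shape)
    if fp == 0 and fn == 0:
        return 1.0
    if dc:
        fp_term = (fp / len(dc)) * sum(
            1.0 / (1.0 + mu_fp * min_dist(p, gt) ** 2) for p in dc)
    else:
        fp_term = 0.0
    fn_term = 0.0
    for p in gt:
        d = min_dist(p, dc)
        if not math.isinf(d):
            fn_term += 1.0 / (1.0 + mu_fn * d**2)
    fn_term *= fn / len(gt)
    return (fp_term + fn_term) / (fp + fn)
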