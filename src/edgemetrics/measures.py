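"""Similarity and dissimilarity measures for binary edge-map pairs.

Given a ground-truth contour map Gt and a candidate map Dc of the same image
grid, the measures here score how well the candidate reproduces — and is
positioned like — the reference shape.  All measures except RDE are normalized
to [0, 1], 1 meaning a perfect match.

Implemented measures (registry names in parentheses):

* Dice (``dice``): pure confusion-count overlap, no distances.
* Pratt's Figure of Merit (``fom``): penalizes false-positive distances only.
* FoM revisited, F (``f``): penalizes false-negative distances only, with the
  false-positive *count* weighted by β in the normalizer.
* d4 (``d4``): a combination of confusion statistics (3/4 weight) and FoM.
* Edge map quality measure Dp (``dp``): FP distances to Gt and FN distances to
  the nearest *correctly detected* pixel (TP).
* Edge Mismatch Measure, EMM (``emm``): TP-gated score with threshold-capped
  FN/FP distance penalties.
* Relative Distance Error, RDE (``rde``): non-normalized sum of the mean
  k-th-power FP-side and FN-side distances.
* The normalized pose measure M (``m``): weights the FP and FN distance sums by
  FP/|Dc| and FN/|Gt| and normalizes by 1/(FP+FN); its scale parameters
  (μFP, μFN) default to (1/Δ², 1/Δ), computed automatically from the ground
  truth, so that μFP < μFN and false negatives are penalized more heavily than
  false positives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .distance import delta_max, diagonal_length, distance_field
from .edgemap import EdgeMap, validate_pair
from .errors import ValidationError

__all__ = [
    "ConfusionCounts",
    "MeasureParams",
    "Score",
    "confusion_counts",
    "dice",
    "fom",
    "f_measure",
    "d4",
    "dp",
    "emm",
    "rde",
    "m_measure",
    "auto_params",
    "score_all",
    "MEASURES",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies for a (Gt, Dc) pair.

    tp: pixels marked in both maps; fp: only in the candidate; fn: only in the
    ground truth; tn: in neither.  tp+fp+fn+tn = |I|, tp+fn = |Gt|,
    tp+fp = |Dc|.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_gt(self) -> int:
        return self.tp + self.fn

    @property
    def n_dc(self) -> int:
        return self.tp + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MeasureParams:
    """All tunables of the measure family.

    kappa : scale of the 1/(1+κ·d²) penalty in FoM, F, d4 and Dp; default 1/9.
    beta : F's weight on the false-positive count; default 1 (unweighted).
    mu_fp, mu_fn : scale parameters of M.  ``None`` (default) means automatic:
        (1/Δ², 1/Δ) with Δ computed from the ground truth, which guarantees
        μFP < μFN whenever Δ > 1.
    emm_mdist, emm_dmax, emm_omega : EMM's threshold schedule.  ``None`` means
        the published defaults Mdist = |I|/40, Dmax = |I|/10, ω = 10/|I|,
        filled in from the image size at call time.  Note |I| is a pixel
        count, so for large images the resulting Mdist exceeds any realizable
        pixel distance and the cap never fires; this follows the published
        schedule as printed.
    emm_epsilon : EMM's relative FP weight; default 2.
    rde_order : exponent k of RDE's power means; default 2.
    rde_root : apply the k-th root to each mean (the established RDE form).
        ``False`` reproduces the plain sum of k-th-power means.
    """

    kappa: float = 1.0 / 9.0
    beta: float = 1.0
    mu_fp: float | None = None
    mu_fn: float | None = None
    emm_mdist: float | None = None
    emm_dmax: float | None = None
    emm_omega: float | None = None
    emm_epsilon: float = 2.0
    rde_order: int = 2
    rde_root: bool = True

    def __post_init__(self):
        for name in ("kappa", "beta", "emm_epsilon"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        for name in ("mu_fp", "mu_fn", "emm_mdist", "emm_dmax", "emm_omega"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.rde_order < 1 or int(self.rde_order) != self.rde_order:
            raise ValidationError("rde_order must be a positive integer")

    def resolve_mu(self, gt: EdgeMap) -> "MeasureParams":
        """Fill in automatic (μFP, μFN) from the ground truth if unset."""
        if self.mu_fp is not None and self.mu_fn is not None:
            return self
        mu_fp, mu_fn = auto_params(gt, mode="delta")
        return replace(
            self,
            mu_fp=self.mu_fp if self.mu_fp is not None else mu_fp,
            mu_fn=self.mu_fn if self.mu_fn is not None else mu_fn,
        )

    def resolve_emm(self, n_pixels: int) -> tuple[float, float, float, float]:
        """EMM's (Mdist, Dmax, ω, ε) with |I|-based defaults filled in."""
        mdist = self.emm_mdist if self.emm_mdist is not None else n_pixels / 40.0
        dmax = self.emm_dmax if self.emm_dmax is not None else n_pixels / 10.0
        omega = self.emm_omega if self.emm_omega is not None else 10.0 / n_pixels
        return mdist, dmax, omega, self.emm_epsilon


@dataclass(frozen=True)
class Score:
    """One measure's result: its registry name, value, and whether the value
    lives on the normalized [0, 1] scale (all measures but RDE)."""

    name: str
    value: float
    normalized: bool = True


def confusion_counts(gt: EdgeMap, dc: EdgeMap) -> ConfusionCounts:
    """TP/FP/FN/TN tallies with set-intersection semantics."""
    validate_pair(gt, dc)
    tp = int(np.count_nonzero(gt.mask & dc.mask))
    fp = int(np.count_nonzero(~gt.mask & dc.mask))
    fn = int(np.count_nonzero(gt.mask & ~dc.mask))
    tn = gt.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# shared distance plumbing


def _fields(gt: EdgeMap, dc: EdgeMap,
            d_gt: np.ndarray | None, d_dc: np.ndarray | None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Distance-to-Gt and distance-to-Dc fields, computing what is missing.

    An empty candidate yields an all-infinite d_Dc: every ground-truth pixel is
    infinitely far from the (nonexistent) detection, the maximal penalty.
    """
    if d_gt is None:
        d_gt = distance_field(gt)
    if d_dc is None:
        d_dc = (np.full(dc.shape, np.inf) if dc.is_empty else distance_field(dc))
    return d_gt, d_dc


def _penalty(dist_sq_scaled: np.ndarray) -> np.ndarray:
    # 1/(1+x) with x possibly inf; inf maps to 0
    with np.errstate(divide="ignore"):
        return 1.0 / (1.0 + dist_sq_scaled)


# ---------------------------------------------------------------------------
# measures


def dice(gt: EdgeMap, dc: EdgeMap, params: MeasureParams | None = None, *,
         d_gt=None, d_dc=None) -> Score:
    """Dice overlap 2·TP / (2·TP + FN + FP)."""
    c = confusion_counts(gt, dc)
    value = 2.0 * c.tp / (2.0 * c.tp + c.fn + c.fp)
    return Score("dice", value)


def fom(gt: EdgeMap, dc: EdgeMap, params: MeasureParams | None = None, *,
        d_gt=None, d_dc=None) -> Score:
    """Pratt's Figure of Merit.

    FoM = 1/max(|Gt|, |Dc|) · Σ_{p∈Dc} 1/(1 + κ·d_Gt(p)²).  True positives
    contribute 1 each (their distance is 0), so equivalently
    FoM = (TP + Σ_{p∈FP} 1/(1+κ·d_Gt(p)²)) / max(|Gt|, |Dc|), and with FP = 0
    the score reduces exactly to TP/|Gt|.
    """
    params = params or MeasureParams()
    validate_pair(gt, dc)
    if d_gt is None:
        d_gt = distance_field(gt)
    denom = max(gt.n_points, dc.n_points)
    s = float(_penalty(params.kappa * d_gt[dc.mask] ** 2).sum())
    return Score("fom", s / denom)


def f_measure(gt: EdgeMap, dc: EdgeMap, params: MeasureParams | None = None, *,
              d_gt=None, d_dc=None) -> Score:
    """FoM revisited: F = 1/(|Gt| + β·FP) · Σ_{p∈Gt} 1/(1 + κ·d_Dc(p)²).

    Records FN distances but not FP distances; FPs enter only through their
    count in the normalizer.  An empty candidate gives F = 0 (all distances
    infinite), the far-separation limit.
    """
    params = params or MeasureParams()
    c = confusion_counts(gt, dc)
    if d_dc is None:
        d_dc = np.full(dc.shape, np.inf) if dc.is_empty else distance_field(dc)
    s = float(_penalty(params.kappa * d_dc[gt.mask] ** 2).sum())
    return Score("f", s / (c.n_gt + params.beta * c.fp))


def d4(gt: EdgeMap, dc: EdgeMap, params: MeasureParams | None = None, *,
       d_gt=None, d_dc=None) -> Score:
    """Combination of confusion statistics and FoM.

    d4 = 1 − ½·sqrt( [(TP − max)² + FN² + FP²]/max² + (1 − FoM)² ) with
    max = max(|Gt|, |Dc|).  Three of the four terms are counts, so the measure
    behaves three-quarters like a statistical score and one quarter like FoM.
    """
    params = params or MeasureParams()
    c = confusion_counts(gt, dc)
    mx = max(c.n_gt, c.n_dc)
    fom_val = fom(gt, dc, params, d_gt=d_gt).value
    stat = ((c.tp - mx) ** 2 + c.fn**2 + c.fp**2) / mx**2
    value = 1.0 - 0.5 * math.sqrt(stat + (1.0 - fom_val) ** 2)
    return Score("d4", value)


def dp(gt: EdgeMap, dc: EdgeMap, params: MeasureParams | None = None, *,
       d_gt=None, d_dc=None) -> Score:
    """Edge map quality measure.

    Dp = 1 − 1/(2(|I|−|Gt|)) · Σ_{p∈FP} (1 − 1/(1+κ·d_Gt(p)²))
           − 1/(2|Gt|)       · Σ_{p∈FN} (1 − 1/(1+κ·d_TP(p)²)),

    where d_TP(p) is the distance from a missed pixel to the nearest correctly
    detected pixel (TP).  When no pixel is correctly detected each FN summand
    takes its supremum 1 (equivalently d_TP = ∞): missed edges are maximally
    penalized when nothing at all was found in the right place.
    """
    params = params or MeasureParams()
    c = confusion_counts(gt, dc)
    if gt.size == c.n_gt:
        raise ValidationError("Dp is undefined when the ground truth fills the image")
    if d_gt is None:
        d_gt = distance_field(gt)

    fp_mask = ~gt.mask & dc.mask
    fp_term = float((1.0 - _penalty(params.kappa * d_gt[fp_mask] ** 2)).sum())
    fp_term /= 2.0 * (gt.size - c.n_gt)

    fn_mask = gt.mask & ~dc.mask
    tp_mask = gt.mask & dc.mask
    if tp_mask.any():
        d_tp = distance_field(EdgeMap(tp_mask))
        fn_term = float((1.0 - _penalty(params.kappa * d_tp[fn_mask] ** 2)).sum())
    else:
        fn_term = float(np.count_nonzero(fn_mask))
    fn_term /= 2.0 * c.n_gt

    return Score("dp", 1.0 - fp_term - fn_term)


def emm(gt: EdgeMap, dc: EdgeMap, params: MeasureParams | None = None, *,
        d_gt=None, d_dc=None) -> Score:
    """Edge Mismatch Measure.

    EMM = TP / ( TP + ω·( Σ_{p∈FN} δ_Dc(p) + ε·Σ_{p∈FP} δ_Gt(p) ) ), where the
    threshold function δ passes a distance through when it is below Mdist and
    replaces it with the cap Dmax otherwise.  The score is 0 whenever not a
    single pixel is correctly detected (TP = 0).
    """
    params = params or MeasureParams()
    c = confusion_counts(gt, dc)
    if c.tp == 0:
        return Score("emm", 0.0)
    mdist, dmax, omega, eps = params.resolve_emm(gt.size)
    d_gt, d_dc = _fields(gt, dc, d_gt, d_dc)

    def delta(d: np.ndarray) -> np.ndarray:
        return np.where(d < mdist, d, dmax)

    fn_sum = float(delta(d_dc[gt.mask & ~dc.mask]).sum())
    fp_sum = float(delta(d_gt[~gt.mask & dc.mask]).sum())
    value = c.tp / (c.tp + omega * (fn_sum + eps * fp_sum))
    return Score("emm", value)


def rde(gt: EdgeMap, dc: EdgeMap, params: MeasureParams | None = None, *,
        d_gt=None, d_dc=None) -> Score:
    """Relative Distance Error (non-normalized).

    RDE = ( 1/|Dc| · Σ_{p∈Dc} d_Gt(p)^k )^(1/k)
        + ( 1/|Gt| · Σ_{p∈Gt} d_Dc(p)^k )^(1/k),

    the sum of the k-th-power means of the FP-side and FN-side distances
    (default k = 2).  Zero iff the maps coincide.  With ``rde_root=False`` the
    roots are dropped and the plain means of d^k are summed.
    """
    params = params or MeasureParams()
    validate_pair(gt, dc)
    if dc.is_empty:
        raise ValidationError("RDE is undefined for an empty candidate map")
    d_gt, d_dc = _fields(gt, dc, d_gt, d_dc)
    k = params.rde_order
    mean_dc = float((d_gt[dc.mask] ** k).mean())
    mean_gt = float((d_dc[gt.mask] ** k).mean())
    if params.rde_root:
        value = mean_dc ** (1.0 / k) + mean_gt ** (1.0 / k)
    else:
        value = mean_dc + mean_gt
    return Score("rde", value, normalized=False)


def m_measure(gt: EdgeMap, dc: EdgeMap, params: MeasureParams | None = None, *,
              d_gt=None, d_dc=None) -> Score:
    """The normalized pose/shape similarity measure M.

    With FP = FN = 0 the score is exactly 1.  Otherwise

    M = 1/(FP+FN) · ( FP/|Dc| · Σ_{p∈Dc} 1/(1+μFP·d_Gt(p)²)
                    + FN/|Gt| · Σ_{p∈Gt} 1/(1+μFN·d_Dc(p)²) ),

    where both sums run over the *whole* candidate and ground-truth sets
    (correctly detected pixels contribute 1 to each sum).  The FP and FN
    distance penalties are weighted by the share of mistakes on each side, and
    1/(FP+FN) normalizes the total into (0, 1].  With the automatic parameters
    μFP = 1/Δ² < μFN = 1/Δ, missed edges cost more than spurious ones.
    """
    params = (params or MeasureParams()).resolve_mu(gt)
    c = confusion_counts(gt, dc)
    if c.fp == 0 and c.fn == 0:
        return Score("m", 1.0)
    d_gt, d_dc = _fields(gt, dc, d_gt, d_dc)

    if c.n_dc > 0:
        fp_term = (c.fp / c.n_dc) * float(
            _penalty(params.mu_fp * d_gt[dc.mask] ** 2).sum())
    else:
        fp_term = 0.0
    fn_term = (c.fn / c.n_gt) * float(
        _penalty(params.mu_fn * d_dc[gt.mask] ** 2).sum())
    return Score("m", (fp_term + fn_term) / (c.fp + c.fn))


def auto_params(gt: EdgeMap, mode: str = "delta",
                fixed: tuple[float, float] | None = None) -> tuple[float, float]:
    """Automatic (μFP, μFN) scale parameters for M.

    mode 'delta'    → (1/Δ², 1/Δ) with Δ the maximum distance-to-Gt in the
                      image — the recommended configuration;
    mode 'diagonal' → (1/D², 1/D) with D the image diagonal;
    mode 'fixed'    → the caller-supplied pair (e.g. (0.1, 0.2)).

    In the automatic modes μFP < μFN holds whenever the scale exceeds 1 pixel,
    so false negatives are penalized more heavily than false positives.
    """
    if mode == "delta":
        scale = delta_max(gt)
        if scale <= 0:
            raise ValidationError("Δ is zero (ground truth covers every pixel); "
                                  "automatic parameters are undefined")
    elif mode == "diagonal":
        scale = diagonal_length(gt.height, gt.width)
    elif mode == "fixed":
        if fixed is None:
            raise ValidationError("mode 'fixed' requires an explicit (mu_fp, mu_fn)")
        mu_fp, mu_fn = fixed
        if mu_fp <= 0 or mu_fn <= 0:
            raise ValidationError("scale parameters must be strictly positive")
        return float(mu_fp), float(mu_fn)
    else:
        raise ValidationError(f"unknown parameter mode {mode!r}; "
                              "expected 'delta', 'diagonal' or 'fixed'")
    return 1.0 / scale**2, 1.0 / scale


MEASURES: dict[str, Callable[..., Score]] = {
    "dice": dice,
    "fom": fom,
    "f": f_measure,
    "d4": d4,
    "dp": dp,
    "emm": emm,
    "rde": rde,
    "m": m_measure,
}


def score_all(gt: EdgeMap, dc: EdgeMap, params: MeasureParams | None = None,
              measures: Sequence[str] | None = None) -> list[Score]:
    """Score one pair with several measures, sharing the two distance fields.

    ``measures`` is a list of registry names (default: all, in registry
    order); results come back in request order and agree exactly with the
    individual calls.
    """
    params = params or MeasureParams()
    validate_pair(gt, dc)
    names = list(MEASURES) if measures is None else list(measures)
    unknown = [n for n in names if n not in MEASURES]
    if unknown:
        raise ValidationError(
            f"unknown measure(s) {unknown}; available: {sorted(MEASURES)}")
    d_gt, d_dc = _fields(gt, dc, None, None)
    params = params.resolve_mu(gt)
    return [MEASURES[n](gt, dc, params, d_gt=d_gt, d_dc=d_dc) for n in names]
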