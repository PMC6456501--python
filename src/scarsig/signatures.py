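"""Supervised mutational-signature decomposition.

A sample's 96-channel catalog column v is modelled as a non-negative linear
combination of known signatures, v ~ W h with h >= 0, fitted by non-negative
least squares (NNLS). To improve specificity the fit runs twice: signatures
whose first-pass relative exposure (h_k / N, N the sample's mutation count)
falls below a signature-specific cutoff are discarded and the reduced set is
refitted. 95% confidence intervals per retained exposure come from profile
likelihoods: the exposure is perturbed and fixed, the remaining exposures are
refitted, residual log-likelihoods under a zero-mean Gaussian are compared by
a likelihood-ratio test, and the interval limits are the perturbations whose
chi-square(1) tail probability equals (1 - level)/2 per side.

The per-signature cutoffs calibrated on 7042 reference tumors against the
COSMIC AC1-AC30 compendium ship as the packaged default cutoff table; a
generic ROC calibrator (Youden's J) is provided for user-labelled cohorts.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, nnls as _scipy_nnls
from scipy.stats import chi2, fisher_exact
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANCE_FLOOR",
    "nnls_fit",
    "two_pass_decompose",
    "profile_likelihood_ci",
    "decompose_with_ci",
    "normalize_exposure_per_mbp",
    "derive_cutoffs",
    "enrichment_test",
    "detection_counts",
    "default_cutoffs",
    "ExposureFit",
    "exposures_to_frame",
    "lrt_threshold",
]

#: floor on the residual-variance estimate, avoids degenerate perfect fits
VARIANCE_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# NNLS and the two-pass filter

def nnls_fit(v: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative least squares: argmin_{h>=0} ||v - W h||_2.

    Returns (exposures, residuals).
    """
    v = np.asarray(v, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or v.shape[0] != W.shape[0]:
        raise ValueError(f"dimension mismatch: v has {v.shape[0]} channels, W {W.shape}")
    if (v < 0).any():
        raise ValueError("catalog column must be non-negative")
    if W.shape[1] == 0:
        return np.zeros(0), v.copy()
    h, _ = _scipy_nnls(W, v)
    return h, v - W @ h


@dataclass
class ExposureFit:
    """Per-sample decomposition result.

    ``absolute`` holds exposures for every signature in the input matrix
    (zero where the two-pass filter removed one); ``retained`` flags the
    signatures kept in the second pass. CI bounds are NaN for signatures
    without an interval.
    """

    sample: str
    signatures: list
    absolute: np.ndarray
    total: float  # N, the sample's mutation count
    retained: np.ndarray
    residuals: np.ndarray
    sigma2: float
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    ci_flags: list  # per signature: None or 'lo-at-boundary'/'hi-at-boundary'

    @property
    def relative(self) -> np.ndarray:
        if self.total <= 0:
            return np.zeros_like(self.absolute)
        return self.absolute / self.total

    @property
    def ci_excludes_zero(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.ci_lo, nan=0.0) > 0


def _gauss_loglik(resid: np.ndarray) -> float:
    s2 = max(float(np.mean(resid**2)), VARIANCE_FLOOR)
    n = resid.size
    return -0.5 * n * (np.log(2 * np.pi * s2) + float(np.mean(resid**2)) / s2)


def two_pass_decompose(
    v: np.ndarray, W: pd.DataFrame, cutoffs: pd.Series
) -> ExposureFit:
    """Two-pass NNLS with per-signature relative-exposure cutoffs.

    Pass 1 fits all signatures; any signature whose relative exposure
    ``h_k / N`` falls below its cutoff is removed; pass 2 refits the reduced
    set. Removed signatures report zero exposure and are flagged not-retained.
    """
    sig_ids = list(W.columns)
    missing = [s for s in sig_ids if s not in cutoffs.index]
    if missing:
        raise ValueError(f"cutoff table missing signatures: {missing}")
    v = np.asarray(v, dtype=float)
    n_total = float(v.sum())
    W_arr = W.to_numpy(dtype=float)
    h1, _ = nnls_fit(v, W_arr)
    rel1 = h1 / n_total if n_total > 0 else np.zeros_like(h1)
    keep = rel1 >= cutoffs.reindex(sig_ids).to_numpy(dtype=float)
    absolute = np.zeros(len(sig_ids))
    if keep.any():
        h2, resid = nnls_fit(v, W_arr[:, keep])
        absolute[keep] = h2
    else:
        warnings.warn("all signatures removed by the cutoff filter")
        resid = v.copy()
    nan = np.full(len(sig_ids), np.nan)
    return ExposureFit(
        sample="",
        signatures=sig_ids,
        absolute=absolute,
        total=n_total,
        retained=keep,
        residuals=resid,
        sigma2=max(float(np.mean(resid**2)), VARIANCE_FLOOR),
        ci_lo=nan.copy(),
        ci_hi=nan.copy(),
        ci_flags=[None] * len(sig_ids),
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals

def lrt_threshold(level: float = 0.95) -> float:
    """Deviance at which the chi-square(1) tail equals the per-side target
    (1 - level)/2; the CI limits solve D(delta) = this value."""
    return float(chi2.isf((1 - level) / 2, df=1))


def profile_likelihood_ci(
    v: np.ndarray,
    W_kept: pd.DataFrame,
    fit: ExposureFit,
    k,
    level: float = 0.95,
    xtol: float = 1e-4,
) -> tuple[float, float, str | None]:
    """Profile-likelihood CI for one retained exposure.

    The exposure to signature ``k`` is fixed at a perturbed value, the other
    retained exposures are refitted by NNLS on the deflated catalog, and the
    residual Gaussian log-likelihoods of initial and alternative models feed a
    likelihood-ratio statistic D (clamped at 0). The limits are the values
    where the chi-square(1) tail of D reaches (1-level)/2, found by bracketed
    root-finding; the lower limit is clamped at 0, the upper at N (flagged).
    """
    kept_ids = [s for s, kp in zip(fit.signatures, fit.retained) if kp]
    if k not in kept_ids:
        raise ValueError(f"signature {k!r} not retained in fit")
    v = np.asarray(v, dtype=float)
    cols = list(W_kept.columns)
    ki = cols.index(k)
    W_arr = W_kept.to_numpy(dtype=float)
    w_k = W_arr[:, ki]
    W_rest = np.delete(W_arr, ki, axis=1)
    h_hat = np.array([fit.absolute[fit.signatures.index(s)] for s in cols])
    ll0 = _gauss_loglik(v - W_arr @ h_hat)
    target = lrt_threshold(level)

    def deviance(x: float) -> float:
        resid_target = v - x * w_k
        if W_rest.shape[1]:
            h_rest, _ = _scipy_nnls(W_rest, resid_target)
            resid = resid_target - W_rest @ h_rest
        else:
            resid = resid_target
        return max(0.0, 2.0 * (ll0 - _gauss_loglik(resid)))

    center = h_hat[ki]
    upper_bound = max(fit.total, center + 1.0)
    flag = None

    def solve(a: float, b: float) -> float:
        return float(brentq(lambda x: deviance(x) - target, a, b, xtol=xtol))

    # lower limit
    if deviance(0.0) <= target:
        lo = 0.0
    else:
        lo = solve(0.0, center)
    # upper limit: expand the bracket geometrically from the estimate
    step = max(1.0, 0.1 * max(center, 1.0))
    b = center + step
    while deviance(b) < target and b < upper_bound:
        step *= 2.0
        b = min(center + step, upper_bound)
    if deviance(b) < target:
        hi = upper_bound
        flag = "hi-at-boundary"
    else:
        hi = solve(center, b)
    return lo, hi, flag


def decompose_with_ci(
    catalog: pd.DataFrame,
    W: pd.DataFrame,
    cutoffs: pd.Series,
    level: float = 0.95,
) -> list[ExposureFit]:
    """Two-pass decomposition plus profile-likelihood CIs for every sample."""
    fits = []
    for sample in catalog.columns:
        v = catalog[sample].to_numpy(dtype=float)
        fit = two_pass_decompose(v, W, cutoffs)
        fit.sample = str(sample)
        kept_ids = [s for s, kp in zip(fit.signatures, fit.retained) if kp]
        W_kept = W[kept_ids]
        for k in kept_ids:
            lo, hi, flag = profile_likelihood_ci(v, W_kept, fit, k, level=level)
            i = fit.signatures.index(k)
            fit.ci_lo[i], fit.ci_hi[i] = lo, hi
            fit.ci_flags[i] = flag
        fits.append(fit)
    return fits


def exposures_to_frame(fits, per_mbp_target: float | None = None) -> pd.DataFrame:
    """Tidy exposure table: one row per (sample, signature)."""
    rows = []
    for fit in fits:
        for i, sig in enumerate(fit.signatures):
            row = {
                "sample": fit.sample,
                "signature": sig,
                "absolute": fit.absolute[i],
                "relative": fit.relative[i],
                "ci_lo": fit.ci_lo[i],
                "ci_hi": fit.ci_hi[i],
                "retained": bool(fit.retained[i]),
                "ci_excludes_zero": bool(fit.ci_excludes_zero[i]),
            }
            if per_mbp_target is not None:
                row["per_mbp"] = normalize_exposure_per_mbp(fit.absolute[i], per_mbp_target)
            rows.append(row)
    return pd.DataFrame(rows)


def normalize_exposure_per_mbp(absolute_exposure: float, target_size_mbp: float) -> float:
    """Exposure per Mbp of sequencing target, making WES and WGS comparable."""
    if target_size_mbp <= 0:
        raise ValueError("target size must be > 0 Mbp")
    return absolute_exposure / target_size_mbp


# ---------------------------------------------------------------------------
# cutoffs

def default_cutoffs() -> pd.Series:
    """The packaged per-signature relative-exposure cutoffs (AC1..AC30),
    calibrated by ROC analysis on 7042 reference tumors."""
    ref = importlib.resources.files("scarsig.data").joinpath("cosmic_cutoffs.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return pd.Series(df.cutoff.to_numpy(), index=df.signature, name="cutoff")


def derive_cutoffs(
    catalog: pd.DataFrame,
    labels: pd.DataFrame,
    W: pd.DataFrame,
    min_informative_j: float = 0.1,
) -> pd.DataFrame:
    """Calibrate relative-exposure cutoffs from a labelled cohort by ROC sweep.

    ``labels`` is samples x signatures boolean (signature truly present).
    For each signature the threshold over first-pass relative exposures that
    maximises Youden's J (sensitivity + specificity - 1) is returned, ties
    broken toward the smaller threshold. Signatures with single-class labels
    get a missing cutoff; best-J below ``min_informative_j`` is flagged
    uninformative.
    """
    zero_cut = pd.Series(0.0, index=W.columns)
    rel = np.column_stack(
        [
            two_pass_decompose(catalog[s].to_numpy(dtype=float), W, zero_cut).relative
            for s in catalog.columns
        ]
    )  # signatures x samples
    rows = []
    for i, sig in enumerate(W.columns):
        if sig not in labels.columns:
            rows.append({"signature": sig, "cutoff": np.nan, "youden_j": np.nan,
                         "informative": False, "note": "unlabelled"})
            continue
        y = labels[sig].reindex(catalog.columns).to_numpy(dtype=bool)
        x = rel[i]
        if y.all() or not y.any():
            rows.append({"signature": sig, "cutoff": np.nan, "youden_j": np.nan,
                         "informative": False, "note": "single-class"})
            continue
        thresholds = np.unique(np.concatenate([[0.0], x]))
        best_j, best_t = -np.inf, 0.0
        for t in thresholds:  # ascending, so ties keep the smaller threshold
            pred = x >= t
            sens = (pred & y).sum() / y.sum()
            spec = (~pred & ~y).sum() / (~y).sum()
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        rows.append(
            {
                "signature": sig,
                "cutoff": best_t,
                "youden_j": best_j,
                "informative": best_j >= min_informative_j,
                "note": "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort enrichment

def detection_counts(fits, criterion: str = "retained") -> pd.Series:
    """Per-signature detected-sample counts.

    ``criterion`` is ``'retained'`` (retained after the two-pass filter with
    nonzero exposure, the default) or ``'ci'`` (95% CI excludes zero).
    """
    if criterion not in ("retained", "ci"):
        raise ValueError("criterion must be 'retained' or 'ci'")
    sigs = fits[0].signatures
    counts = np.zeros(len(sigs), dtype=int)
    for fit in fits:
        if criterion == "retained":
            counts += (fit.retained & (fit.absolute > 0)).astype(int)
        else:
            counts += fit.ci_excludes_zero.astype(int)
    return pd.Series(counts, index=sigs, name="detected")


def enrichment_test(counts: pd.DataFrame) -> pd.DataFrame:
    """Fisher exact enrichment of per-signature detection versus a background.

    ``counts`` needs columns cohort_detected, cohort_total, background_detected,
    background_total (one row per signature). Adds two-sided Fisher p and
    Benjamini-Hochberg q across all tested signatures.
    """
    ps, flags = [], []
    for r in counts.itertuples():
        table = [
            [r.cohort_detected, r.cohort_total - r.cohort_detected],
            [r.background_detected, r.background_total - r.background_detected],
        ]
        if min(r.cohort_total, r.background_total) <= 0:
            ps.append(1.0)
            flags.append("zero-total")
            continue
        if min(min(row) for row in table) < 0:
            raise ValueError("detected counts exceed totals")
        ps.append(float(fisher_exact(table, alternative="two-sided")[1]))
        flags.append("")
    out = counts.copy()
    out["p"] = ps
    out["q"] = multipletests(ps, method="fdr_bh")[1]
    out["flag"] = flags
    return out
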