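"""Differential-expression testing and gene-signature construction.

Genes differentially expressed between recurrent and non-recurrent
training samples are found by two-group t-tests on normalized log2
expression; a signature is the set of genes below a raw p-value cutoff.
No multiple-testing correction is applied: the cutoff acts as a tuning
parameter of the classifier, not as an inference claim.

Fold changes follow the signed convention common in qPCR reports: the
log2 group difference d is reported as 2**d when d >= 0 and -2**(-d)
otherwise, so |fold| >= 1 always and the sign tracks the direction of
change in the recurrent group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .data_model import ExpressionMatrix

__all__ = [
    "GeneTestResult",
    "Signature",
    "EmptySignatureError",
    "two_group_t_test",
    "signed_fold_change",
    "select_signature",
    "pearson_correlation",
]


class EmptySignatureError(ValueError):
    """No gene passed the p-value cutoff; classification is undefined."""


@dataclass
class GeneTestResult:
    gene_id: str
    mean_recurrent: float
    mean_nonrecurrent: float
    t_statistic: float
    p_value: float
    signed_fold_change: float


@dataclass
class Signature:
    """Ordered gene set (ascending p) with the per-gene test results."""

    gene_ids: list[str]
    p_cutoff: float
    results: list[GeneTestResult]

    def __len__(self) -> int:
        return len(self.gene_ids)


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Signed linear fold change from two log2 means (a relative to b)."""
    r = 2.0 ** (float(mean_a) - float(mean_b))
    return r if r >= 1.0 else -1.0 / r


def _censored_lrt(a, b, a_detected, b_detected, bound):
    """Likelihood-ratio test with left-censoring at ``bound``.

    Both groups share a variance; non-detects contribute Phi((bound-mu)/sd)
    terms.  Returns a signed sqrt(chi-square) statistic and a two-sided p
    from the 1-df chi-square reference.  This is an approximation to
    censored-ML group comparison, not a replica of any particular package.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a_det = np.ones(a.shape, bool) if a_detected is None else np.asarray(a_detected, bool)
    b_det = np.ones(b.shape, bool) if b_detected is None else np.asarray(b_detected, bool)

    def negll(params, split):
        if split:
            mu_a, mu_b, log_sd = params
        else:
            mu_a = mu_b = params[0]
            log_sd = params[1]
        sd = np.exp(log_sd)
        ll = 0.0
        for x, d, mu in ((a, a_det, mu_a), (b, b_det, mu_b)):
            obs = x[d]
            ll += np.sum(stats.norm.logpdf(obs, mu, sd))
            n_cens = int((~d).sum())
            if n_cens:
                ll += n_cens * stats.norm.logcdf(bound, mu, sd)
        return -ll

    obs_all = np.concatenate([a[a_det], b[b_det]])
    if obs_all.size < 2:
        raise ValueError("censored t-test needs >= 2 detected values overall")
    mu0 = float(obs_all.mean())
    sd0 = float(max(obs_all.std(), 1e-3))
    mu_a0 = float(a[a_det].mean()) if a_det.any() else mu0
    mu_b0 = float(b[b_det].mean()) if b_det.any() else mu0
    r0 = minimize(negll, [mu0, np.log(sd0)], args=(False,), method="Nelder-Mead",
                  options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    r1 = minimize(negll, [mu_a0, mu_b0, np.log(sd0)],
                  args=(True,), method="Nelder-Mead",
                  options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    chi2 = max(2.0 * (r0.fun - r1.fun), 0.0)
    p = float(stats.chi2.sf(chi2, df=1))
    sign = np.sign(r1.x[0] - r1.x[1]) or 1.0
    return float(sign * np.sqrt(chi2)), p


def two_group_t_test(
    expr_a,
    expr_b,
    variant: str = "welch",
    a_detected=None,
    b_detected=None,
    bound: Optional[float] = None,
) -> tuple[float, float]:
    """Two-tailed two-group location test; returns ``(t, p)``.

    ``welch`` uses Satterthwaite degrees of freedom, ``pooled`` uses
    n_a + n_b - 2; ``censored`` maximizes a Gaussian likelihood with
    left-censored terms at ``bound`` (required) and compares null vs
    split-mean fits by a 1-df likelihood ratio.  Two groups with zero
    variance and equal means give t=0, p=1.
    """
    a = np.asarray(expr_a, float)
    b = np.asarray(expr_b, float)
    if variant == "censored":
        if bound is None:
            raise ValueError("censored variant requires a detection bound")
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs >= 2 values")
        return _censored_lrt(a, b, a_detected, b_detected, bound)
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 finite values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("t-test inputs must be finite")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def select_signature(
    expr: ExpressionMatrix,
    labels: Mapping[str, bool],
    p_cutoff: float,
    variant: str = "welch",
    bounds: Optional[Sequence[float]] = None,
) -> Signature:
    """Signature = genes with p strictly below ``p_cutoff``, ordered by p.

    ``labels`` maps every sample id to True (recurrent) / False.  For the
    censored variant, ``bounds`` gives the per-sample detection limit in
    expression units and the matrix's non-detect flags are honored.

    Raises :class:`EmptySignatureError` if no gene passes.
    """
    if not (0.0 < p_cutoff < 1.0):
        raise ValueError("p_cutoff must be in (0, 1)")
    missing = [s for s in expr.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"labels missing for samples: {missing}")
    rec_mask = np.array([bool(labels[s]) for s in expr.sample_ids])
    results = []
    for i, gene in enumerate(expr.gene_ids):
        row = expr.expr[i]
        det = expr.detected[i]
        a, b = row[rec_mask], row[~rec_mask]
        if variant == "censored":
            bvec = None if bounds is None else np.asarray(bounds, float)
            t, p = two_group_t_test(
                np.where(det[rec_mask], a, 0.0), np.where(det[~rec_mask], b, 0.0),
                variant="censored",
                a_detected=det[rec_mask], b_detected=det[~rec_mask],
                bound=float(np.min(bvec)) if bvec is not None else float(np.nanmin(row[det])),
            )
            mean_a = float(a[det[rec_mask]].mean())
            mean_b = float(b[det[~rec_mask]].mean())
        else:
            t, p = two_group_t_test(a, b, variant=variant)
            mean_a, mean_b = float(a.mean()), float(b.mean())
        results.append(GeneTestResult(
            gene_id=gene,
            mean_recurrent=mean_a,
            mean_nonrecurrent=mean_b,
            t_statistic=t,
            p_value=p,
            signed_fold_change=signed_fold_change(mean_a, mean_b),
        ))
    passing = sorted(
        (r for r in results if r.p_value < p_cutoff),
        key=lambda r: (r.p_value, r.gene_id),
    )
    if not passing:
        raise EmptySignatureError(
            f"no gene has p < {p_cutoff} among {len(results)} tested"
        )
    return Signature(
        gene_ids=[r.gene_id for r in passing],
        p_cutoff=p_cutoff,
        results=passing,
    )


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two paired vectors (>= 3 pairs)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.var() == 0.0 or y.var() == 0.0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def signature_report_rows(sig: Signature) -> list[dict]:
    """Rows for the signature report table (gene, means, t, p, signed fold)."""
    return [
        {
            "gene": r.gene_id,
            "mean_recurrent": r.mean_recurrent,
            "mean_nonrecurrent": r.mean_nonrecurrent,
            "t": r.t_statistic,
            "p": r.p_value,
            "signed_fold_change": r.signed_fold_change,
        }
        for r in sig.results
    ]
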