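"""Reference-gene normalization and non-detect handling.

qPCR non-detects are informatively missing: a reaction is more likely to
fail when the transcript is scarce, so replacing failed wells with the
maximum cycle number biases group means.  Two treatments are provided:

* ``substitute_ceiling`` — the conventional "Ct 40" substitution
  (the unimputed arm of the data-handling comparison);
* ``impute_nondetects`` — an EM fit of a Gaussian expression model per
  gene/group combined with a logistic detection model shared across genes,
  imputing each non-detect with its conditional expectation.

The missingness model is Pr(non-detect | y) = 1 / (1 + exp(-(b0 + b1*y)))
on normalized log2 expression y; with b1 < 0 detection improves with
expression, which is the mechanism the EM is designed to undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .data_model import CtMatrix, ExpressionMatrix

__all__ = [
    "ImputationModel",
    "normalize_to_reference",
    "substitute_ceiling",
    "impute_nondetects",
]

DEFAULT_REFERENCE = "BECN1"

# 64-point Gauss-Hermite rule: the conditional-expectation integrals are
# smooth (Gaussian x logistic) and this makes the E-step deterministic.
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(64)


def normalize_to_reference(ct: CtMatrix, reference_gene: str = DEFAULT_REFERENCE) -> ExpressionMatrix:
    """Delta-Ct normalization: expr[g, s] = ct[ref, s] - ct[g, s].

    Higher values mean more expressed (log2 fold over the reference gene).
    The reference row is dropped; non-detect cells stay flagged (NaN) for
    downstream imputation or substitution.

    Raises ``KeyError`` if the reference gene is absent and ``ValueError``
    (naming the sample) if the reference is non-detect anywhere.
    """
    r = ct.gene_index(reference_gene)
    bad = [s for j, s in enumerate(ct.sample_ids) if not ct.detected[r, j]]
    if bad:
        raise ValueError(
            f"reference gene {reference_gene!r} is non-detect in sample(s): {bad}"
        )
    keep = [i for i in range(ct.n_genes) if i != r]
    expr = ct.ct[r, :][None, :] - ct.ct[keep, :]
    detected = ct.detected[keep, :]
    expr = np.where(detected, expr, np.nan)
    return ExpressionMatrix(
        gene_ids=[ct.gene_ids[i] for i in keep],
        sample_ids=list(ct.sample_ids),
        expr=expr,
        provenance="unimputed",
        detected=detected,
    )


def substitute_ceiling(ct: CtMatrix, max_cycle: float = 40.0) -> CtMatrix:
    """Set every non-detect to ``max_cycle`` and mark it detected."""
    new_ct = ct.ct.copy()
    new_ct[~ct.detected] = max_cycle
    return CtMatrix(
        gene_ids=list(ct.gene_ids),
        sample_ids=list(ct.sample_ids),
        ct=new_ct,
        detected=np.ones_like(ct.detected, dtype=bool),
    )


@dataclass
class ImputationModel:
    """Fitted parameters of the EM non-detect model.

    ``means`` is genes x groups (group-specific means of log2 expression),
    ``variances`` a pooled per-gene variance; ``beta0``/``beta1`` the
    logistic detection parameters shared across genes.
    """

    gene_ids: list[str]
    group_names: list[str]
    means: np.ndarray
    variances: np.ndarray
    beta0: float
    beta1: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    def pooled_gene_mean(self, gene_index: int, group_sizes: Optional[Sequence[int]] = None) -> float:
        mu = self.means[gene_index]
        if group_sizes is None:
            return float(np.mean(mu))
        w = np.asarray(group_sizes, dtype=float)
        return float(np.sum(mu * w) / np.sum(w))

    def conditional_nondetect_mean(self, gene_index: int, group_index: int = 0) -> float:
        """E[y | non-detect] under the fitted model for one gene/group."""
        mu = self.means[gene_index, group_index]
        sd = float(np.sqrt(self.variances[gene_index]))
        e_y, _ = _nondetect_moments(mu, sd, self.beta0, self.beta1)
        return float(e_y)


def _nondetect_moments(mu: float, sd: float, beta0: float, beta1: float):
    """Posterior mean and second moment of y given a non-detect.

    Posterior density is proportional to N(y; mu, sd^2) * sigmoid(b0+b1*y);
    integrals via the probabilists' Gauss-Hermite rule.
    """
    y = mu + sd * _GH_NODES
    w = _GH_WEIGHTS * expit(beta0 + beta1 * y)
    z = np.sum(w)
    if z <= 0 or not np.isfinite(z):
        # detection model says non-detects are impossible here; fall back
        # to the prior mean
        return mu, mu * mu + sd * sd
    w = w / z
    e_y = float(np.sum(w * y))
    e_y2 = float(np.sum(w * y * y))
    return e_y, e_y2


def _nondetect_logprob(mu: np.ndarray, sd: np.ndarray, beta0: float, beta1: float) -> np.ndarray:
    """log Pr(non-detect) = log integral N(y; mu, sd^2) sigmoid(b0+b1*y) dy."""
    mu = np.atleast_1d(mu)
    sd = np.atleast_1d(sd)
    y = mu[:, None] + sd[:, None] * _GH_NODES[None, :]
    # probabilists' rule: weights sum to sqrt(2*pi), so dividing by that sum
    # integrates against the N(mu, sd^2) density
    z = np.sum(_GH_WEIGHTS[None, :] * expit(beta0 + beta1 * y), axis=1)
    z = z / np.sum(_GH_WEIGHTS)
    return np.log(np.maximum(z, 1e-300))


def _observed_loglik(y_obs, mu_obs, sd_obs, mu_nd, sd_nd, beta0, beta1) -> float:
    ll = 0.0
    if y_obs.size:
        ll += float(np.sum(
            -0.5 * np.log(2 * np.pi * sd_obs**2)
            - 0.5 * ((y_obs - mu_obs) / sd_obs) ** 2
            + log_expit(-(beta0 + beta1 * y_obs))
        ))
    if mu_nd.size:
        ll += float(np.sum(_nondetect_logprob(mu_nd, sd_nd, beta0, beta1)))
    return ll


def _fit_beta(y0: np.ndarray, y1: np.ndarray, w1: np.ndarray, start) -> tuple[float, float]:
    """Weighted logistic M-step: responses 0 at y0 (detected, weight 1) and
    1 at y1 with weights w1 (posterior mass at quadrature nodes).  A weak
    L2 penalty keeps the optimum finite when one class is absent."""

    def neg_q(b):
        b0, b1 = b
        q = 0.0
        if y0.size:
            q += float(np.sum(log_expit(-(b0 + b1 * y0))))
        if y1.size:
            q += float(np.sum(w1 * log_expit(b0 + b1 * y1)))
        return -(q - 1e-6 * (b0 * b0 + b1 * b1))

    res = minimize(neg_q, np.asarray(start, dtype=float), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    return float(res.x[0]), float(res.x[1])


def impute_nondetects(
    ct: CtMatrix,
    reference_gene: str = DEFAULT_REFERENCE,
    labels: Optional[Mapping[str, bool]] = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: Optional[int] = None,
) -> tuple[ExpressionMatrix, ImputationModel]:
    """EM imputation of non-detects on reference-normalized expression.

    Parameters
    ----------
    ct : CtMatrix
        Raw Ct values with the non-detect mask.
    reference_gene : str
        Housekeeping reference; must be detected in every sample.
    labels : mapping sample_id -> bool, optional
        Group membership (e.g. recurred) used for group-specific gene
        means; with no labels a single group is fit per gene.
    seed : int, optional
        Jitters the initial detection-model parameters only; the E-step
        itself is deterministic quadrature.

    Returns
    -------
    (ExpressionMatrix, ImputationModel)
        Fully imputed expression (provenance ``"imputed"``) and the fitted
        model, whose ``converged`` flag is False if ``max_iter`` was hit.

    Raises
    ------
    ValueError
        If any gene has zero detected values across the cohort.
    """
    norm = normalize_to_reference(ct, reference_gene)
    y = norm.expr  # genes x samples, NaN where non-detect
    det = norm.detected
    n_genes, n_samples = y.shape

    for i, g in enumerate(norm.gene_ids):
        if not det[i].any():
            raise ValueError(f"gene {g!r} has zero detected values")

    if labels is None:
        group_of = np.zeros(n_samples, dtype=int)
        group_names = ["all"]
    else:
        group_of = np.array(
            [1 if labels[s] else 0 for s in norm.sample_ids], dtype=int
        )
        group_names = ["nonrecurrent", "recurrent"]
    n_groups = len(group_names)
    group_masks = [group_of == k for k in range(n_groups)]

    # --- initialization ---------------------------------------------------
    means = np.zeros((n_genes, n_groups))
    variances = np.zeros(n_genes)
    overall = np.array([np.nanmean(np.where(det[i], y[i], np.nan)) for i in range(n_genes)])
    for i in range(n_genes):
        resid = []
        for k, m in enumerate(group_masks):
            obs = y[i, m & det[i]]
            means[i, k] = obs.mean() if obs.size else overall[i]
            resid.extend(obs - means[i, k])
        v = np.var(resid) if len(resid) > 1 else 1.0
        variances[i] = max(v, 1e-4)
    rng = np.random.default_rng(seed)
    beta0, beta1 = -2.0 + 0.01 * rng.standard_normal(), -0.5 + 0.01 * rng.standard_normal()

    nd_cells = [(i, j) for i in range(n_genes) for j in range(n_samples) if not det[i, j]]
    y_obs_flat = y[det]

    trace: list[float] = []
    converged = False
    n_iter = 0
    e_mean = {}
    for it in range(1, max_iter + 1):
        n_iter = it
        # --- E-step: posterior moments for every non-detect cell ----------
        e_mean = {}
        e_sq = {}
        nd_nodes = []
        nd_node_weights = []
        for (i, j) in nd_cells:
            mu = means[i, group_of[j]]
            sd = float(np.sqrt(variances[i]))
            nodes = mu + sd * _GH_NODES
            w = _GH_WEIGHTS * expit(beta0 + beta1 * nodes)
            z = w.sum()
            if z <= 0 or not np.isfinite(z):
                w = _GH_WEIGHTS / _GH_WEIGHTS.sum()
            else:
                w = w / z
            e_mean[(i, j)] = float(np.sum(w * nodes))
            e_sq[(i, j)] = float(np.sum(w * nodes * nodes))
            nd_nodes.append(nodes)
            nd_node_weights.append(w)

        # --- M-step: gene/group means, pooled gene variance ---------------
        for i in range(n_genes):
            sq_sum = 0.0
            n_cells = 0
            for k, m in enumerate(group_masks):
                idx = np.where(m)[0]
                if idx.size == 0:
                    continue
                vals = [
                    y[i, j] if det[i, j] else e_mean[(i, j)] for j in idx
                ]
                means[i, k] = float(np.mean(vals))
                for j in idx:
                    if det[i, j]:
                        sq_sum += (y[i, j] - means[i, k]) ** 2
                    else:
                        sq_sum += (
                            e_sq[(i, j)]
                            - 2.0 * means[i, k] * e_mean[(i, j)]
                            + means[i, k] ** 2
                        )
                n_cells += idx.size
            variances[i] = max(sq_sum / max(n_cells, 1), 1e-6)

        # --- M-step: shared logistic detection model ----------------------
        if nd_cells:
            y1 = np.concatenate(nd_nodes)
            w1 = np.concatenate(nd_node_weights)
        else:
            y1 = np.empty(0)
            w1 = np.empty(0)
        beta0, beta1 = _fit_beta(y_obs_flat, y1, w1, (beta0, beta1))

        # --- observed-data log-likelihood ---------------------------------
        mu_obs = np.zeros_like(y)
        for k, m in enumerate(group_masks):
            mu_obs[:, m] = means[:, [k]]
        sd_all = np.sqrt(variances)[:, None] * np.ones_like(y)
        ll = _observed_loglik(
            y[det], mu_obs[det], sd_all[det],
            mu_obs[~det], sd_all[~det], beta0, beta1,
        )
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    if not nd_cells:
        converged = True

    expr = y.copy()
    for (i, j) in nd_cells:
        # final imputation at the converged parameters
        mu = means[i, group_of[j]]
        sd = float(np.sqrt(variances[i]))
        expr[i, j], _ = _nondetect_moments(mu, sd, beta0, beta1)

    model = ImputationModel(
        gene_ids=list(norm.gene_ids),
        group_names=group_names,
        means=means,
        variances=variances,
        beta0=beta0,
        beta1=beta1,
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
    )
    out = ExpressionMatrix(
        gene_ids=list(norm.gene_ids),
        sample_ids=list(norm.sample_ids),
        expr=expr,
        provenance="imputed",
    )
    return out, model
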