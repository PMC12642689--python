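"""Per-site empirical-Bayes posterior dN/dS tracks.

NEB (naive empirical Bayes) evaluates the posterior over site classes at
the maximum-likelihood estimates:

    P(k | site) = w_k L_k(site) / sum_j w_j L_j(site).

grid-BEB additionally averages the NEB posteriors over a uniform grid of
the hyperparameters that control the positive class, weighting each grid
point by its integrated likelihood — a coarse account of hyperparameter
uncertainty in the spirit of Bayes empirical Bayes.  Sites with
P(omega > 1) above 0.9 are flagged significant, the conventional
threshold for calling positive selection on individual sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from selstruct.codon_evo.fit import SiteModelFit
from selstruct.codon_evo.likelihood import ArrayTree, log_likelihood
from selstruct.codon_evo.model import SiteClassMixture
from selstruct.seqdata import CodonAlignment

SIGNIFICANCE_THRESHOLD = 0.9
_GRID_POINTS = 8


@dataclass
class SitePosteriorTrack:
    """Per-codon-site posterior class weights and derived summaries."""

    class_posteriors: np.ndarray  # (n_sites, n_classes)
    class_omegas: np.ndarray
    post_mean_omega: np.ndarray
    prob_positive: np.ndarray
    method: str
    model_tag: str
    significance_threshold: float = SIGNIFICANCE_THRESHOLD
    significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.prob_positive > self.significance_threshold

    @property
    def n_sites(self) -> int:
        return len(self.post_mean_omega)

    def to_frame(self) -> pd.DataFrame:
        """1-based per-site table as exported to TSV."""
        return pd.DataFrame(
            {
                "site": np.arange(1, self.n_sites + 1),
                "post_mean_omega": self.post_mean_omega,
                "prob_positive": self.prob_positive,
                "significant": self.significant,
                "method": self.method,
                "model": self.model_tag,
            }
        )


def _neb_summaries(
    weights: np.ndarray, omegas: np.ndarray, site_class_lik: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    post = weights[:, None] * site_class_lik  # (K, n_sites)
    total = post.sum(axis=0)
    total = np.where(total > 0, total, 1.0)
    post = (post / total).T  # (n_sites, K)
    post_mean = post @ omegas
    prob_pos = post[:, omegas > 1.0].sum(axis=1)
    return post, post_mean, prob_pos


def site_posteriors(
    fit: SiteModelFit,
    aln: CodonAlignment,
    tree: ArrayTree | None = None,
    method: str = "NEB",
) -> SitePosteriorTrack:
    """Posterior mean omega and P(omega > 1) per codon site.

    ``method="NEB"`` uses the MLEs directly; ``method="grid-BEB"``
    (M7/M8 only) averages over an 8-point-per-axis uniform hyperparameter
    grid — (p, q) for M7, (p0, omega_s) for M8 with (p, q) held at their
    MLEs — weighted by integrated likelihood.
    """
    tree = tree if tree is not None else fit.tree
    _, f = log_likelihood(aln, tree, fit.mixture, fit.kappa, fit.pi)
    if method == "NEB":
        post, post_mean, prob_pos = _neb_summaries(
            fit.mixture.class_weights, fit.mixture.class_omegas, f
        )
        return SitePosteriorTrack(
            post, fit.mixture.class_omegas, post_mean, prob_pos, "NEB", fit.model_tag
        )
    if method != "grid-BEB":
        raise ValueError(f"unknown posterior method {method!r}")
    if fit.model_tag not in ("M7", "M8"):
        raise ValueError("grid-BEB is defined for the beta-family models M7/M8")
    k_beta = (
        fit.mixture.n_classes
        if fit.model_tag == "M7"
        else fit.mixture.n_classes - 1
    )
    sp = fit.mixture.shape_params
    mids = (np.arange(_GRID_POINTS) + 0.5) / _GRID_POINTS
    grids: list[SiteClassMixture] = []
    if fit.model_tag == "M7":
        for p in 2.0 * mids:  # uniform over (0, 2], the informative shape range
            for q in 2.0 * mids:
                grids.append(SiteClassMixture.m7(p, q, k_beta))
    else:
        for p0 in mids:
            for ws in 1.0 + 10.0 * mids:  # uniform over (1, 11]
                grids.append(SiteClassMixture.m8(sp["p"], sp["q"], p0, ws, k_beta))
    ells = np.empty(len(grids))
    means = np.empty((len(grids), f.shape[1]))
    probs = np.empty_like(means)
    for g, mixture in enumerate(grids):
        ell, fg = log_likelihood(aln, tree, mixture, fit.kappa, fit.pi)
        ells[g] = ell
        _, means[g], probs[g] = _neb_summaries(
            mixture.class_weights, mixture.class_omegas, fg
        )
    w = np.exp(ells - ells.max())
    w /= w.sum()
    post_mean = w @ means
    prob_pos = w @ probs
    # class-level posterior averaged on the MLE class grid is not defined
    # across grid points; report the NEB class posterior alongside.
    neb_post, _, _ = _neb_summaries(
        fit.mixture.class_weights, fit.mixture.class_omegas, f
    )
    return SitePosteriorTrack(
        neb_post, fit.mixture.class_omegas, post_mean, prob_pos, "grid-BEB", fit.model_tag
    )
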