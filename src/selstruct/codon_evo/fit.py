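"""Maximum-likelihood fitting of codon site models.

All fits use bounded quasi-Newton (L-BFGS-B) on transformed parameters
(rate parameters in log space, proportions on the raw simplex with
bounds).  Branch lengths are optimized jointly under M0 and then fixed
for the site-model fits by default (``branch_policy="M0-fixed"``), the
standard practice for this model family; ``"joint"`` re-optimizes them
per model.  Additional deterministic starting points are tried when a
fit fails to converge; warm starts from the nested null model guarantee
the nesting inequality up to optimizer tolerance and are used by
:func:`fit_lrt_pair`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from selstruct.codon_evo.likelihood import (
    ArrayTree,
    MixtureEngine,
    compress_patterns,
    encode_alignment,
    site_class_likelihoods,
    _LOG_FLOOR,
)
from selstruct.codon_evo.model import SiteClassMixture, codon_frequencies
from selstruct.seqdata import CodonAlignment

KAPPA_BOUNDS = (0.01, 50.0)
OMEGA_BOUNDS = (1e-4, 20.0)
OMEGA_S_BOUNDS = (1.0 + 1e-6, 20.0)
BETA_SHAPE_BOUNDS = (0.005, 99.0)
BRANCH_BOUNDS = (1e-6, 20.0)
PROP_BOUNDS = (1e-4, 1.0 - 1e-4)

_BIG = 1e10
_OPT_OPTIONS = {"maxiter": 500, "ftol": 1e-10, "maxfun": 5000}


@dataclass
class SiteModelFit:
    """One fitted site model: parameters, mixture, and log-likelihood."""

    model_tag: str
    mixture: SiteClassMixture
    kappa: float
    pi: np.ndarray
    tree: ArrayTree
    log_likelihood: float
    converged: bool
    n_params: int
    branch_lengths_optimized: bool
    pi_mode: str = "F3x4"
    trace: dict = field(default_factory=dict)

    @property
    def omega(self) -> float:
        """Whole-gene average dN/dS (mixture mean omega)."""
        return float(self.mixture.class_weights @ self.mixture.class_omegas)


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested site models: 2*delta-ell vs chi2."""

    stat: float
    df: int
    p_value: float
    null_tag: str = ""
    alt_tag: str = ""


def lrt(null: SiteModelFit, alt: SiteModelFit, df: int | None = None) -> LRTResult:
    """Chi-square LRT; the statistic is clamped at 0 (boundary cases are
    conservative; no mixture-boundary correction is applied)."""
    if df is None:
        df = alt.n_params - null.n_params
    delta = alt.log_likelihood - null.log_likelihood
    if delta < -0.1:
        raise RuntimeError(
            f"alternative log-likelihood below null by {-delta:.3f}; "
            "optimizer failure, refit advised"
        )
    stat = max(0.0, 2.0 * delta)
    return LRTResult(
        stat=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
        null_tag=null.model_tag,
        alt_tag=alt.model_tag,
    )


# ---------------------------------------------------------------------
# Internal machinery
# ---------------------------------------------------------------------

class _Data:
    """Pattern-compressed alignment reused across objective evaluations."""

    def __init__(self, aln: CodonAlignment, sites: np.ndarray | None = None):
        codes = encode_alignment(aln)
        if sites is not None:
            codes = codes[:, sites]
        self.patterns, self.weights, self.inverse = compress_patterns(codes)
        self.genetic_code = aln.genetic_code

    def ell(self, tree: ArrayTree, mixture: SiteClassMixture, kappa: float, pi: np.ndarray) -> float:
        engine = MixtureEngine(mixture, kappa, pi, self.genetic_code)
        f = site_class_likelihoods(self.patterns, tree, engine)
        mix = mixture.class_weights @ f
        return float(self.weights @ np.log(np.maximum(mix, _LOG_FLOOR)))


def _log_bounds(bounds: tuple[float, float]) -> tuple[float, float]:
    return (np.log(bounds[0]), np.log(bounds[1]))


def _minimize(obj: Callable, x0: np.ndarray, bounds: list[tuple[float, float]]):
    x0 = np.clip(np.asarray(x0, float), [b[0] for b in bounds], [b[1] for b in bounds])
    return minimize(obj, x0, method="L-BFGS-B", bounds=bounds, options=_OPT_OPTIONS)


def _multistart(obj, starts, bounds, max_starts: int = 3, min_starts: int = 1):
    """Run deterministic starts, keeping the best objective value seen.

    At least ``min_starts`` are always evaluated (mixtures with a
    positive class have flat boundary optima that can trap a single
    start); further starts run only while no start has converged.
    """
    best = None
    for i, x0 in enumerate(list(starts)[:max_starts]):
        if i >= min_starts and best is not None and best.success and np.isfinite(best.fun):
            break
        res = _minimize(obj, x0, bounds)
        if best is None or res.fun < best.fun:
            best = res
    return best


def _safe(obj: Callable) -> Callable:
    def wrapped(x):
        try:
            val = obj(x)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return _BIG
        return val if np.isfinite(val) else _BIG

    return wrapped


# ---------------------------------------------------------------------
# Mixture builders keyed by model tag
# ---------------------------------------------------------------------

def _mixture_from_theta(tag: str, theta: np.ndarray, k: int) -> tuple[SiteClassMixture, float]:
    """Decode (mixture, kappa) from the transformed parameter vector."""
    kappa = float(np.exp(theta[0]))
    if tag == "M0":
        return SiteClassMixture.m0(float(np.exp(theta[1]))), kappa
    if tag == "M1":
        return SiteClassMixture.m1(float(np.exp(theta[1])), float(theta[2])), kappa
    if tag == "M2":
        omega0 = float(np.exp(theta[1]))
        x0, x1 = float(theta[2]), float(theta[3])
        p0, p1 = x0, (1.0 - x0) * x1
        return SiteClassMixture.m2(omega0, p0, p1, float(theta[4])), kappa
    if tag == "M7":
        return SiteClassMixture.m7(float(np.exp(theta[1])), float(np.exp(theta[2])), k), kappa
    if tag == "M8":
        return (
            SiteClassMixture.m8(
                float(np.exp(theta[1])),
                float(np.exp(theta[2])),
                float(theta[3]),
                float(theta[4]),
                k,
            ),
            kappa,
        )
    raise ValueError(f"unknown model tag {tag!r}")


def _theta_spec(tag: str) -> tuple[list[tuple[float, float]], int]:
    """Bounds for the transformed parameter vector and free-param count."""
    lk = _log_bounds(KAPPA_BOUNDS)
    lo = _log_bounds(OMEGA_BOUNDS)
    lb = _log_bounds(BETA_SHAPE_BOUNDS)
    if tag == "M0":
        return [lk, lo], 2
    if tag == "M1":
        return [lk, (lo[0], np.log(1.0 - 1e-6)), PROP_BOUNDS], 3
    if tag == "M2":
        return [lk, (lo[0], np.log(1.0 - 1e-6)), PROP_BOUNDS, PROP_BOUNDS, OMEGA_S_BOUNDS], 5
    if tag == "M7":
        return [lk, lb, lb], 3
    if tag == "M8":
        return [lk, lb, lb, PROP_BOUNDS, OMEGA_S_BOUNDS], 5
    raise ValueError(f"unknown model tag {tag!r}")


def _default_starts(tag: str, kappa0: float, warm: SiteModelFit | None) -> list[np.ndarray]:
    lk = np.log(kappa0)
    starts: list[np.ndarray] = []
    if warm is not None:
        wk = np.log(warm.kappa)
        sp = warm.mixture.shape_params
        if tag == "M1" and warm.model_tag == "M0":
            w0 = min(warm.omega, 0.9)
            starts.append(np.array([wk, np.log(max(w0, 1e-3)), 0.8]))
        elif tag == "M2" and warm.model_tag == "M1":
            w0 = warm.mixture.class_omegas[0]
            p0 = warm.mixture.class_weights[0]
            starts.append(
                np.array([wk, np.log(max(w0, 1e-3)), min(p0, 1 - 1e-4), 1 - 1e-4, 2.0])
            )
        elif tag == "M8" and warm.model_tag == "M7":
            starts.append(
                np.array(
                    [wk, np.log(sp["p"]), np.log(sp["q"]), 1.0 - 1e-4, 2.0]
                )
            )
    if tag == "M0":
        starts += [np.array([lk, np.log(0.4)]), np.array([lk, np.log(0.05)]),
                   np.array([np.log(2.0), np.log(1.5)])]
    elif tag == "M1":
        starts += [np.array([lk, np.log(0.2), 0.7]), np.array([lk, np.log(0.05), 0.9])]
    elif tag == "M2":
        starts += [np.array([lk, np.log(0.2), 0.6, 0.7, 2.5]),
                   np.array([lk, np.log(0.05), 0.8, 0.5, 4.0])]
    elif tag == "M7":
        starts += [np.array([lk, np.log(0.5), np.log(1.5)]),
                   np.array([lk, np.log(2.0), np.log(5.0)]),
                   np.array([lk, np.log(0.2), np.log(0.5)])]
    elif tag == "M8":
        starts += [np.array([lk, np.log(0.5), np.log(1.5), 0.85, 3.0]),
                   np.array([lk, np.log(2.0), np.log(5.0), 0.95, 1.5])]
    return starts


# ---------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------

def fit_M0(
    aln: CodonAlignment,
    tree: ArrayTree,
    pi_mode: str = "F3x4",
    max_starts: int = 3,
) -> SiteModelFit:
    """Whole-gene average dN/dS: joint ML fit of kappa, a single omega,
    and all branch lengths.

    Degenerate inputs (identical sequences) drive branch lengths to the
    lower bound; the fit is returned flagged rather than raised.
    """
    pi = codon_frequencies(aln, pi_mode)
    data = _Data(aln)
    nb = tree.n_branches
    lbb = _log_bounds(BRANCH_BOUNDS)
    bounds, n_free = _theta_spec("M0")
    bounds = bounds + [lbb] * nb

    def obj(x):
        mixture, kappa = _mixture_from_theta("M0", x[:2], 1)
        t = tree.with_branch_vector(np.exp(x[2:]))
        return -data.ell(t, mixture, kappa, pi)

    b0 = tree.branch_vector()
    init_b = np.where(b0 > 0, b0, 0.1)
    starts = [
        np.concatenate([s, np.log(init_b * f)])
        for s, f in zip(_default_starts("M0", 2.0, None), [1.0, 3.0, 0.2])
    ]
    res = _multistart(_safe(obj), starts, bounds, max_starts)
    mixture, kappa = _mixture_from_theta("M0", res.x[:2], 1)
    fitted_tree = tree.with_branch_vector(np.exp(res.x[2:]))
    # near-zero tree length: omega is unidentifiable (identical sequences)
    degenerate = bool(np.all(np.exp(res.x[2:]) <= 1e-4))
    return SiteModelFit(
        model_tag="M0",
        mixture=mixture,
        kappa=kappa,
        pi=pi,
        tree=fitted_tree,
        log_likelihood=-res.fun,
        converged=bool(res.success) and not degenerate,
        n_params=n_free + nb,
        branch_lengths_optimized=True,
        pi_mode=pi_mode,
        trace={"nit": int(res.nit), "message": str(res.message),
               "degenerate": degenerate},
    )


def fit_site_model(
    aln: CodonAlignment,
    tree: ArrayTree,
    model_tag: str,
    n_beta_classes: int = 10,
    branch_policy: str = "M0-fixed",
    pi_mode: str = "F3x4",
    m0_fit: SiteModelFit | None = None,
    warm_start: SiteModelFit | None = None,
    max_starts: int = 3,
) -> SiteModelFit:
    """Fit one of the site-class mixtures M1, M2, M7, M8 (or M0).

    ``branch_policy="M0-fixed"`` (default) fixes branch lengths at their
    M0 estimates (``m0_fit`` is computed if not supplied); ``"joint"``
    re-optimizes them together with the model parameters.
    ``warm_start`` seeds the search from a nested null fit.
    """
    if model_tag not in ("M0", "M1", "M2", "M7", "M8"):
        raise ValueError(f"unknown model tag {model_tag!r}")
    if n_beta_classes < 2:
        raise ValueError("n_beta_classes must be >= 2")
    if branch_policy not in ("M0-fixed", "joint"):
        raise ValueError(f"unknown branch policy {branch_policy!r}")
    if branch_policy == "M0-fixed":
        if m0_fit is None:
            m0_fit = fit_M0(aln, tree, pi_mode)
        base_tree = m0_fit.tree
        kappa0 = m0_fit.kappa
    else:
        base_tree = tree
        kappa0 = 2.0
    pi = codon_frequencies(aln, pi_mode)
    data = _Data(aln)
    bounds, n_free = _theta_spec(model_tag)
    joint = branch_policy == "joint"
    nb = base_tree.n_branches
    if joint:
        lbb = _log_bounds(BRANCH_BOUNDS)
        bounds = bounds + [lbb] * nb
    n_theta = len(_theta_spec(model_tag)[0])

    def obj(x):
        mixture, kappa = _mixture_from_theta(model_tag, x[:n_theta], n_beta_classes)
        t = base_tree.with_branch_vector(np.exp(x[n_theta:])) if joint else base_tree
        return -data.ell(t, mixture, kappa, pi)

    starts = _default_starts(model_tag, kappa0, warm_start)
    if joint:
        b0 = base_tree.branch_vector()
        init_b = np.log(np.where(b0 > 0, b0, 0.1))
        starts = [np.concatenate([s, init_b]) for s in starts]
    min_starts = 2 if model_tag in ("M2", "M8") else 1
    res = _multistart(_safe(obj), starts, bounds, max_starts, min_starts)
    mixture, kappa = _mixture_from_theta(model_tag, res.x[:n_theta], n_beta_classes)
    fitted_tree = (
        base_tree.with_branch_vector(np.exp(res.x[n_theta:])) if joint else base_tree
    )
    return SiteModelFit(
        model_tag=model_tag,
        mixture=mixture,
        kappa=kappa,
        pi=pi,
        tree=fitted_tree,
        log_likelihood=-res.fun,
        converged=bool(res.success),
        n_params=n_free + (nb if joint else 0),
        branch_lengths_optimized=joint,
        pi_mode=pi_mode,
        trace={"nit": int(res.nit), "message": str(res.message),
               "branch_policy": branch_policy},
    )


def fit_lrt_pair(
    aln: CodonAlignment,
    tree: ArrayTree,
    null_tag: str,
    alt_tag: str,
    n_beta_classes: int = 10,
    pi_mode: str = "F3x4",
    m0_fit: SiteModelFit | None = None,
) -> tuple[SiteModelFit, SiteModelFit, LRTResult]:
    """Fit a nested pair (M1 vs M2 or M7 vs M8) and run the LRT.

    The alternative is warm-started from the null MLE, which both speeds
    the fit and enforces the nesting inequality.  Both pairings use
    chi-square df = 2.
    """
    if (null_tag, alt_tag) not in (("M1", "M2"), ("M7", "M8")):
        raise ValueError("supported pairings: M1 vs M2, M7 vs M8")
    if m0_fit is None:
        m0_fit = fit_M0(aln, tree, pi_mode)
    null = fit_site_model(
        aln, tree, null_tag, n_beta_classes, "M0-fixed", pi_mode, m0_fit
    )
    alt = fit_site_model(
        aln, tree, alt_tag, n_beta_classes, "M0-fixed", pi_mode, m0_fit,
        warm_start=null,
    )
    return null, alt, lrt(null, alt, df=2)


# ---------------------------------------------------------------------
# Fixed-site partition models
# ---------------------------------------------------------------------

@dataclass
class PartitionScheme:
    """A label per codon site (0-based); contiguity not required."""

    labels: list[str]

    def __post_init__(self) -> None:
        self.groups: dict[str, np.ndarray] = {}
        arr = np.asarray(self.labels)
        for lab in dict.fromkeys(self.labels):  # preserve first-seen order
            self.groups[lab] = np.where(arr == lab)[0]
        if len(self.groups) < 2:
            raise ValueError("partition tests need >= 2 non-empty partitions")


@dataclass
class FixedSiteResult:
    partition_omegas: dict[str, float]
    shared_omega: float
    kappa_alt: float
    kappa_null: float
    ell_alt: float
    ell_null: float
    lrt: LRTResult
    warnings: list[str]


def fit_fixed_sites(
    aln: CodonAlignment,
    tree: ArrayTree,
    scheme: PartitionScheme,
    pi_mode: str = "F3x4",
    m0_fit: SiteModelFit | None = None,
) -> FixedSiteResult:
    """Partitioned fixed-site model: one omega per partition vs a shared
    omega, kappa and branch lengths common to all partitions.

    Branch lengths are fixed at the whole-alignment M0 estimates; the
    LRT has df = (number of partitions - 1).
    """
    if len(scheme.labels) != aln.site_count:
        raise ValueError("partition labels must cover every codon site")
    warns: list[str] = []
    for lab, sites in scheme.groups.items():
        if len(sites) < 10:
            msg = f"partition {lab!r} has only {len(sites)} codon sites; unstable estimate"
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
    if m0_fit is None:
        m0_fit = fit_M0(aln, tree, pi_mode)
    base_tree = m0_fit.tree
    pi = codon_frequencies(aln, pi_mode)
    datasets = {lab: _Data(aln, sites) for lab, sites in scheme.groups.items()}
    labs = list(datasets)
    m = len(labs)
    lk = _log_bounds(KAPPA_BOUNDS)
    lo = _log_bounds(OMEGA_BOUNDS)

    def obj_alt(x):
        kappa = float(np.exp(x[0]))
        total = 0.0
        for i, lab in enumerate(labs):
            mixture = SiteClassMixture.m0(float(np.exp(x[1 + i])))
            total += datasets[lab].ell(base_tree, mixture, kappa, pi)
        return -total

    def obj_null(x):
        kappa = float(np.exp(x[0]))
        mixture = SiteClassMixture.m0(float(np.exp(x[1])))
        return -sum(d.ell(base_tree, mixture, kappa, pi) for d in datasets.values())

    lkap = np.log(m0_fit.kappa)
    lom = np.log(max(m0_fit.omega, 1e-3))
    res_null = _multistart(
        _safe(obj_null),
        [np.array([lkap, lom]), np.array([lkap, np.log(0.3)])],
        [lk, lo],
    )
    res_alt = _multistart(
        _safe(obj_alt),
        [np.concatenate([[lkap], np.full(m, lom)]),
         np.concatenate([[lkap], np.linspace(np.log(0.05), np.log(1.5), m)])],
        [lk] + [lo] * m,
    )
    null_fit = SiteModelFit(
        "M0", SiteClassMixture.m0(float(np.exp(res_null.x[1]))),
        float(np.exp(res_null.x[0])), pi, base_tree, -res_null.fun,
        bool(res_null.success), 2, False, pi_mode,
    )
    alt_fit = SiteModelFit(
        "fixed-sites", SiteClassMixture.m0(float(np.exp(res_alt.x[1]))),
        float(np.exp(res_alt.x[0])), pi, base_tree, -res_alt.fun,
        bool(res_alt.success), 1 + m, False, pi_mode,
    )
    test = lrt(null_fit, alt_fit, df=m - 1)
    return FixedSiteResult(
        partition_omegas={lab: float(np.exp(res_alt.x[1 + i])) for i, lab in enumerate(labs)},
        shared_omega=float(np.exp(res_null.x[1])),
        kappa_alt=float(np.exp(res_alt.x[0])),
        kappa_null=float(np.exp(res_null.x[0])),
        ell_alt=-res_alt.fun,
        ell_null=-res_null.fun,
        lrt=test,
        warnings=warns,
    )


# ---------------------------------------------------------------------
# Pairwise dN/dS
# ---------------------------------------------------------------------

@dataclass
class PairwiseDnDs:
    dN: float
    dS: float
    omega: float
    t: float
    kappa: float
    omega_defined: bool
    n_shared_sites: int


def pairwise_dnds(
    aln: CodonAlignment,
    taxon_a: str,
    taxon_b: str,
    pi_mode: str = "F3x4",
) -> PairwiseDnDs:
    """ML pairwise dN and dS on a two-taxon tree (model-0 style).

    dS (dN) is the expected number of synonymous (nonsynonymous)
    substitutions per synonymous (nonsynonymous) site, with site
    proportions computed from the mutational model at omega = 1; their
    ratio equals the fitted omega.  ``omega_defined`` is False when
    dS is effectively 0 (identical or synonymous-invariant sequences).
    """
    ia, ib = aln.taxon_index(taxon_a), aln.taxon_index(taxon_b)
    sa, sb = aln.sequences[ia], aln.sequences[ib]
    cols = [
        c
        for c in range(aln.site_count)
        if "-" not in sa[3 * c : 3 * c + 3] and "-" not in sb[3 * c : 3 * c + 3]
    ]
    if not cols:
        raise ValueError("no shared non-gap codon sites")
    sub = CodonAlignment(
        [taxon_a, taxon_b],
        ["".join(s[3 * c : 3 * c + 3] for c in cols) for s in (sa, sb)],
        genetic_code=aln.genetic_code,
    )
    pi = codon_frequencies(sub, pi_mode)
    data = _Data(sub)
    tree = ArrayTree.two_taxon([taxon_a, taxon_b], 0.1)
    lk = _log_bounds(KAPPA_BOUNDS)
    lo = _log_bounds(OMEGA_BOUNDS)
    lt = _log_bounds(BRANCH_BOUNDS)

    def obj(x):
        kappa, omega, t = np.exp(x)
        t2 = tree.with_branch_vector(np.array([t, 0.0]))
        return -data.ell(t2, SiteClassMixture.m0(float(omega)), float(kappa), pi)

    res = _multistart(
        _safe(obj),
        [np.log([2.0, 0.5, 0.2]), np.log([2.0, 0.05, 0.5]), np.log([1.0, 1.0, 0.05])],
        [lk, lo, lt],
    )
    kappa, omega, t = (float(v) for v in np.exp(res.x))
    from selstruct.codon_evo.model import build_rate_matrix

    fitted = build_rate_matrix(kappa, omega, pi, aln.genetic_code)
    syn_flow, nonsyn_flow = fitted.flows()
    neutral = build_rate_matrix(kappa, 1.0, pi, aln.genetic_code)
    f_syn, f_nonsyn = neutral.flows()
    dS = t * syn_flow / (3.0 * f_syn)
    dN = t * nonsyn_flow / (3.0 * f_nonsyn)
    identical = sub.sequences[0] == sub.sequences[1]
    defined = dS > 1e-7 and not identical
    if identical:
        dN = dS = t = 0.0
    return PairwiseDnDs(
        dN=dN,
        dS=dS,
        omega=omega if defined else float("nan"),
        t=t,
        kappa=kappa,
        omega_defined=defined,
        n_shared_sites=len(cols),
    )
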