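"""Goldman–Yang codon rate matrices and site-class mixtures.

The instantaneous rate between sense codons *i* and *j* differing at a
single nucleotide position is

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

zero for multi-nucleotide changes, with the diagonal set so rows sum to 0
and the matrix scaled so the expected substitution rate -sum_i pi_i q_ii
equals 1 (branch lengths are expected substitutions per codon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

from selstruct._codes import get_code, single_step_table
from selstruct.seqdata import CodonAlignment, GAP_CODON

FREQ_FLOOR = 1e-6


@dataclass
class CodonRateModel:
    """A reversible single-omega codon rate matrix with its parameters."""

    kappa: float
    omega: float
    pi: np.ndarray
    Q: np.ndarray
    genetic_code: int = 1

    def flows(self) -> tuple[float, float]:
        """Expected synonymous and nonsynonymous flux per unit time.

        With the mean-rate-1 normalization the two fluxes sum to 1.
        """
        pairs, kind = single_step_table(self.genetic_code)
        flux = self.pi[pairs[:, 0]] * self.Q[pairs[:, 0], pairs[:, 1]]
        syn = float(flux[kind < 2].sum())
        nonsyn = float(flux[kind >= 2].sum())
        return syn, nonsyn


def build_rate_matrix(
    kappa: float,
    omega: float,
    pi: np.ndarray,
    genetic_code: int = 1,
    *,
    normalize: bool = True,
) -> CodonRateModel:
    """Build the GY94 rate matrix for one site class.

    ``pi`` must be a probability simplex over the sense codons with no
    zeros (the likelihood is undefined for observed codons of frequency
    zero; apply the pseudocount floor upstream).
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = np.asarray(pi, dtype=float)
    n = get_code(genetic_code).n_codons
    if pi.shape != (n,) or not np.isclose(pi.sum(), 1.0):
        raise ValueError(f"pi must be a simplex of length {n}")
    if np.any(pi <= 0):
        raise ValueError("pi entries must be strictly positive")
    pairs, kind = single_step_table(genetic_code)
    factor = np.array([1.0, kappa, omega, omega * kappa])
    Q = np.zeros((n, n))
    Q[pairs[:, 0], pairs[:, 1]] = pi[pairs[:, 1]] * factor[kind]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mean_rate = -(pi * np.diag(Q)).sum()
        if mean_rate <= 0:
            raise ValueError("degenerate rate matrix (zero mean rate)")
        Q /= mean_rate
    return CodonRateModel(kappa=kappa, omega=omega, pi=pi, Q=Q, genetic_code=genetic_code)


def codon_frequencies(
    aln: CodonAlignment,
    mode: str = "F3x4",
    pseudocount_floor: float = FREQ_FLOOR,
) -> np.ndarray:
    """Equilibrium sense-codon frequencies from alignment composition.

    Modes: ``Fequal`` (uniform), ``F1x4`` (overall nucleotide
    frequencies), ``F3x4`` (position-specific nucleotide frequencies),
    ``Fcodon`` (observed codon counts).  After removing stop codons the
    simplex is floored at ``pseudocount_floor`` and renormalized, so no
    sense codon has probability zero.
    """
    code = get_code(aln.genetic_code)
    n = code.n_codons
    if mode == "Fequal":
        pi = np.full(n, 1.0 / n)
        return pi
    nuc_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    if mode in ("F1x4", "F3x4"):
        counts = np.zeros((3, 4))
        for seq in aln.sequences:
            for col in range(len(seq) // 3):
                codon = seq[3 * col : 3 * col + 3]
                if codon == GAP_CODON:
                    continue
                for pos, nt in enumerate(codon):
                    counts[pos, nuc_idx[nt]] += 1
        if mode == "F1x4":
            total = counts.sum(axis=0)
            freq = np.tile(total / total.sum(), (3, 1))
        else:
            freq = counts / counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                freq[0, nuc_idx[c[0]]] * freq[1, nuc_idx[c[1]]] * freq[2, nuc_idx[c[2]]]
                for c in code.codons
            ]
        )
    elif mode == "Fcodon":
        pi = np.zeros(n)
        for seq in aln.sequences:
            for col in range(len(seq) // 3):
                codon = seq[3 * col : 3 * col + 3]
                if codon != GAP_CODON:
                    pi[code.index[codon]] += 1
    else:
        raise ValueError(f"unknown frequency mode {mode!r}")
    total = pi.sum()
    if total <= 0:
        pi = np.full(n, 1.0 / n)
    else:
        pi = pi / total
    pi = np.maximum(pi, pseudocount_floor)
    return pi / pi.sum()


def discretize_beta(p: float, q: float, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """K equal-probability classes for a beta(p, q) omega distribution.

    Class omega values are the medians of the K equal-mass bins
    (quantiles (2i+1)/(2K)), the deterministic discretization convention
    of the site-model family.
    """
    if k < 2:
        raise ValueError("need at least 2 discretization classes")
    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    omegas = beta_dist.ppf(quantiles, p, q)
    weights = np.full(k, 1.0 / k)
    return omegas, weights


@dataclass
class SiteClassMixture:
    """A mixture of omega site classes defining one site model.

    ``model_tag`` is one of M0, M1, M2, M7, M8 (M1/M2 in their modern
    M1a/M2a form with the purifying-class omega estimated).
    ``shape_params`` carries (p, q) for M7/M8 and additionally
    (p0, omega_s) for M8.
    """

    class_omegas: np.ndarray
    class_weights: np.ndarray
    model_tag: str
    shape_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.class_omegas = np.asarray(self.class_omegas, dtype=float)
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if self.class_omegas.shape != self.class_weights.shape:
            raise ValueError("class omega / weight shape mismatch")
        if np.any(self.class_weights < -1e-12):
            raise ValueError("negative class weight")
        if not np.isclose(self.class_weights.sum(), 1.0):
            raise ValueError("class weights must sum to 1")
        if np.any(self.class_omegas < 0):
            raise ValueError("negative class omega")

    @property
    def n_classes(self) -> int:
        return len(self.class_omegas)

    # -- constructors --------------------------------------------------
    @staticmethod
    def m0(omega: float) -> "SiteClassMixture":
        return SiteClassMixture(np.array([omega]), np.array([1.0]), "M0")

    @staticmethod
    def m1(omega0: float, p0: float) -> "SiteClassMixture":
        return SiteClassMixture(
            np.array([omega0, 1.0]), np.array([p0, 1.0 - p0]), "M1"
        )

    @staticmethod
    def m2(omega0: float, p0: float, p1: float, omega2: float) -> "SiteClassMixture":
        return SiteClassMixture(
            np.array([omega0, 1.0, omega2]),
            np.array([p0, p1, 1.0 - p0 - p1]),
            "M2",
        )

    @staticmethod
    def m7(p: float, q: float, k: int = 10) -> "SiteClassMixture":
        om, w = discretize_beta(p, q, k)
        return SiteClassMixture(om, w, "M7", {"p": p, "q": q})

    @staticmethod
    def m8(p: float, q: float, p0: float, omega_s: float, k: int = 10) -> "SiteClassMixture":
        if omega_s < 1.0:
            raise ValueError("M8 positive-class omega must be >= 1")
        om, w = discretize_beta(p, q, k)
        return SiteClassMixture(
            np.append(om, omega_s),
            np.append(w * p0, 1.0 - p0),
            "M8",
            {"p": p, "q": q, "p0": p0, "omega_s": omega_s},
        )
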