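"""2^4 factorial design and regression of melting temperatures.

The 16 combinatorial variants of the four D1-switch sites (mutations
I4V, F26L, Y33F, F37I) form a full two-level factorial.  Each variant's
melting temperature is modelled as

    Tm_i = Constant + sum_j beta_j * F_j + sum_{j<k} beta_jk * F_j F_k
           + ... + beta_1234 * F_1 F_2 F_3 F_4 + eps_i,

where F_j in {0, 1} indicates presence of mutation j (ZERO_ONE coding)
or in {-1/2, +1/2} (CENTERED coding, under which each main-effect
contrast averages a mutation's effect over its 8 background contexts).
Ordinary least squares on per-replicate observations yields the
coefficients in degrees, their standard errors, Student t statistics and
two-sided P values; backward elimination with weak heredity reduces the
saturated model.

Variant indexing: the barcode bits are ordered (I4, F26, Y33, F37) with
I4 the least-significant bit, so wild type is index 0, I4V alone index 1,
and the quadruple mutant index 15.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

SITES = ("I4", "F26", "Y33", "F37")
MUTATIONS = ("I4V", "F26L", "Y33F", "F37I")

#: fixed term order: constant, 4 mains, 6 pairs, 4 triples, quadruple
TERMS: tuple[tuple[int, ...], ...] = tuple(
    subset
    for size in range(5)
    for subset in itertools.combinations(range(4), size)
)

TERM_NAMES: tuple[str, ...] = tuple(
    "Constant" if not t else "*".join(SITES[i] for i in t) for t in TERMS
)

N_TERMS = len(TERMS)  # 16


class DesignError(ValueError):
    """Fatal problem with the design or the regression inputs."""


@dataclass(frozen=True)
class VariantBarcode:
    """4-bit mutation indicator for one variant (1 = mutation present)."""

    indicators: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.indicators) != 4 or any(
            b not in (0, 1) for b in self.indicators
        ):
            raise DesignError(f"barcode must be four 0/1 bits: {self.indicators}")

    @property
    def variant_index(self) -> int:
        return sum(b << i for i, b in enumerate(self.indicators))

    @classmethod
    def from_index(cls, index: int) -> "VariantBarcode":
        if not 0 <= index <= 15:
            raise DesignError(f"variant index out of range: {index}")
        return cls(tuple((index >> i) & 1 for i in range(4)))

    def __str__(self) -> str:
        muts = [MUTATIONS[i] for i, b in enumerate(self.indicators) if b]
        return "WT" if not muts else "/".join(muts)


ALL_VARIANTS: tuple[VariantBarcode, ...] = tuple(
    VariantBarcode.from_index(i) for i in range(16)
)


@dataclass
class DesignMatrix:
    """Factorial predictor matrix (n rows x 16 terms, fixed term order)."""

    X: np.ndarray
    variants: tuple[VariantBarcode, ...]
    coding: str  # ZERO_ONE | CENTERED
    term_names: tuple[str, ...] = TERM_NAMES

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


def design_row(barcode: VariantBarcode, coding: str = "ZERO_ONE") -> np.ndarray:
    """One variant's row over the 16 factorial terms."""
    if coding == "ZERO_ONE":
        levels = np.array(barcode.indicators, dtype=float)
    elif coding == "CENTERED":
        levels = np.array(barcode.indicators, dtype=float) - 0.5
    else:
        raise DesignError(f"unknown coding {coding!r}")
    row = np.empty(N_TERMS)
    for j, term in enumerate(TERMS):
        row[j] = np.prod(levels[list(term)]) if term else 1.0
    return row


def build_design_matrix(variants: Sequence[VariantBarcode] = ALL_VARIANTS,
                        coding: str = "ZERO_ONE") -> DesignMatrix:
    """Stack design rows for a set of distinct variants.

    ``variants`` may repeat the same barcode only via explicit replicate
    expansion (see :func:`replicate_design`); duplicates here are fatal.
    """
    idx = [v.variant_index for v in variants]
    if len(set(idx)) != len(idx):
        raise DesignError("duplicate variants in design")
    X = np.vstack([design_row(v, coding) for v in variants])
    return DesignMatrix(X=X, variants=tuple(variants), coding=coding)


def replicate_design(design: DesignMatrix, n_replicates: int) -> DesignMatrix:
    """Repeat each variant's row for per-replicate observations."""
    X = np.repeat(design.X, n_replicates, axis=0)
    variants = tuple(
        v for v in design.variants for _ in range(n_replicates)
    )
    return DesignMatrix(X=X, variants=variants, coding=design.coding)


@dataclass
class RegressionFit:
    """OLS fit of Tm on the factorial design.

    All arrays span the full 16-term order; entries for terms outside the
    retained set are NaN (coefficients) with ``retained`` False.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    P: np.ndarray
    retained: np.ndarray  # bool mask over TERMS
    R2: float
    rmse: float
    df_resid: int
    residuals: np.ndarray
    coding: str
    term_names: tuple[str, ...] = TERM_NAMES

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_names,
                "beta_C": self.beta,
                "se_C": self.se,
                "t": self.t,
                "P": self.P,
                "retained": self.retained,
            }
        )


def _ols(Xr: np.ndarray, y: np.ndarray):
    model = sm.OLS(y, Xr)
    return model.fit()


def fit_factorial(X: DesignMatrix, tm: Sequence[float],
                  retained: Optional[np.ndarray] = None) -> RegressionFit:
    """Ordinary least squares of Tm observations on the factorial terms.

    ``tm`` has one entry per design row (per-replicate rows give the
    residual degrees of freedom needed for Student tests of the saturated
    model).  With zero residual degrees of freedom the coefficients are
    still returned but SE/t/P are NaN.
    """
    y = np.asarray(tm, dtype=float)
    if y.ndim != 1 or y.size != X.n_obs:
        raise DesignError(
            f"tm length {y.size} does not match design rows {X.n_obs}"
        )
    if retained is None:
        retained = np.ones(N_TERMS, dtype=bool)
    retained = np.asarray(retained, dtype=bool)
    Xr = X.X[:, retained]
    k = int(retained.sum())
    if y.size < k:
        raise DesignError("fewer observations than fitted terms")
    if np.linalg.matrix_rank(Xr) < k:
        raise DesignError("design matrix is rank deficient")

    beta = np.full(N_TERMS, np.nan)
    se = np.full(N_TERMS, np.nan)
    tval = np.full(N_TERMS, np.nan)
    pval = np.full(N_TERMS, np.nan)

    res = _ols(Xr, y)
    beta[retained] = res.params
    df_resid = int(res.df_resid)
    if df_resid > 0:
        se[retained] = res.bse
        tval[retained] = res.tvalues
        pval[retained] = res.pvalues
    fitted = Xr @ res.params
    residuals = y - fitted
    sstot = float(np.sum((y - y.mean()) ** 2))
    ssres = float(np.sum(residuals**2))
    r2 = 1.0 - ssres / sstot if sstot > 0 else 1.0
    rmse = float(np.sqrt(ssres / df_resid)) if df_resid > 0 else float(
        np.sqrt(ssres / y.size)
    )
    return RegressionFit(
        beta=beta, se=se, t=tval, P=pval, retained=retained,
        R2=r2, rmse=rmse, df_resid=df_resid, residuals=residuals,
        coding=X.coding,
    )


def _hereditary_protected(term_idx: int, retained: np.ndarray,
                          P: np.ndarray, p_sig: float) -> bool:
    """Weak heredity: a term is protected while a retained significant
    higher-order term contains it."""
    term = set(TERMS[term_idx])
    for j, other in enumerate(TERMS):
        if j == term_idx or not retained[j]:
            continue
        if term < set(other) and np.isfinite(P[j]) and P[j] < p_sig:
            return True
    return False


def reduce_model(fit: RegressionFit, X: DesignMatrix, tm: Sequence[float],
                 p_remove: float = 0.5, p_sig: float = 0.05) -> RegressionFit:
    """Backward elimination of non-significant terms.

    Repeatedly removes the single highest-P term with P > ``p_remove``,
    refitting after each removal, but never removes a term contained in a
    retained significant (P < ``p_sig``) higher-order term, and never the
    constant.  Terminates when no removable term remains; may retain all
    terms.
    """
    current = fit
    while True:
        cand = [
            j for j in range(1, N_TERMS)
            if current.retained[j]
            and np.isfinite(current.P[j]) and current.P[j] > p_remove
            and not _hereditary_protected(j, current.retained, current.P, p_sig)
        ]
        if not cand:
            return current
        drop = max(cand, key=lambda j: current.P[j])
        logger.debug("dropping term %s (P=%.3f)", TERM_NAMES[drop],
                     current.P[drop])
        retained = current.retained.copy()
        retained[drop] = False
        current = fit_factorial(X, tm, retained=retained)


def batch_align(tm_batch_a, tm_batch_b) -> tuple[float, pd.Series]:
    """Estimate and remove a single additive between-batch offset.

    Both inputs are per-variant Tm values (pandas Series indexed by
    variant index, or equal-length arrays indexed implicitly).  The
    offset is the mean over shared variants of (a - b); batch b is
    shifted by +offset so the two batches can be pooled.
    """
    a = pd.Series(tm_batch_a, dtype=float)
    b = pd.Series(tm_batch_b, dtype=float)
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise DesignError("batches share no variants; cannot align")
    if len(shared) < 4:
        raise DesignError(
            f"only {len(shared)} shared variants; need at least 4 to align"
        )
    if len(shared) < max(len(a), len(b)):
        warnings.warn(
            f"batches overlap on {len(shared)} variants only", stacklevel=2
        )
    offset = float((a.loc[shared] - b.loc[shared]).mean())
    return offset, b + offset


def predict_tm(fit: RegressionFit, barcode: VariantBarcode) -> float:
    """Predicted Tm for one variant from the retained coefficients."""
    row = design_row(barcode, fit.coding)
    beta = np.where(fit.retained, fit.beta, 0.0)
    return float(row @ beta)
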