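"""Relative abundance level (RAL) and studentized-residual (SR) scoring.

RAL is the mean number of unique peptides per MS data set (zeros included):
a cheap spectral-counting index of protein abundance.  Because larger
proteins yield more tryptic peptides, raw counts confound abundance with
protein mass.  The SR score removes that confound: log10 peptide count is
regressed on log10 molecular mass (optionally adjusting for functional class
and data set as factors), and each observation's *externally* studentized
residual measures how far the protein sits above or below the count expected
for its mass, in units of its leave-one-out residual standard deviation.
A protein of average abundance for its mass scores 0; positive means more
abundant than expected, negative less.

The least-squares fit, hat diagonal and external studentization are computed
here directly (QR factorization and the standard leave-one-out variance
downdate) — the per-observation diagnostic is the statistic this package
exists for, and tests pin it against an explicit refit oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FUNCTIONAL_CLASSES


@dataclass
class AbundanceObservation:
    """One nonzero (protein, data set) peptide count with its covariates."""

    locus_tag: str
    dataset_id: str
    peptide_count: int
    mass_kda: float
    functional_class: str = "UK"

    def __post_init__(self) -> None:
        if self.peptide_count < 1:
            raise ValueError("zero-count cells are not observations")
        if self.mass_kda <= 0:
            raise ValueError("mass_kda must be positive")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class {self.functional_class!r}")


@dataclass
class ModelFit:
    """A fitted log–log count model with leverage diagnostics."""

    observations: list[AbundanceObservation]
    column_names: list[str]
    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    leverages: np.ndarray
    df_resid: int

    @property
    def n_params(self) -> int:
        return len(self.column_names)

    @property
    def sse(self) -> float:
        return float(self.residuals @ self.residuals)

    @property
    def sigma(self) -> float:
        """Residual scale s = sqrt(SSE / df_resid)."""
        return float(np.sqrt(self.sse / self.df_resid))

    @property
    def slope_log_mass(self) -> float:
        return float(self.coefficients[self.column_names.index("log10_mass")])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.column_names,
                             "estimate": self.coefficients})


@dataclass
class AbundanceResult:
    """Per-protein abundance report row: RAL plus mean SR."""

    locus_tag: str
    ral: float
    sr: float | None
    n_obs: int


def compute_ral(counts_per_dataset: list[int]) -> float:
    """Mean unique-peptide count over all data sets, zeros included."""
    if len(counts_per_dataset) == 0:
        raise ValueError("RAL needs at least one data set")
    if any(c < 0 for c in counts_per_dataset):
        raise ValueError("counts must be non-negative")
    return float(sum(counts_per_dataset)) / len(counts_per_dataset)


# ---------------------------------------------------------------------------
# model fitting


def _design_matrix(observations: list[AbundanceObservation], multivariable: bool
                   ) -> tuple[np.ndarray, list[str]]:
    n = len(observations)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    cols.append(np.log10([o.mass_kda for o in observations]))
    names.append("log10_mass")
    if multivariable:
        for field_name, getter in (("class", lambda o: o.functional_class),
                                   ("dataset", lambda o: o.dataset_id)):
            levels = sorted({getter(o) for o in observations})
            for lev in levels[1:]:  # first level is the reference
                cols.append(np.array([1.0 if getter(o) == lev else 0.0
                                      for o in observations]))
                names.append(f"{field_name}[{lev}]")
    return np.column_stack(cols), names


def _first_aliased(X: np.ndarray, names: list[str]) -> str:
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            return names[j]
        rank = new_rank
    return names[-1]


def fit_loglog_model(observations: list[AbundanceObservation],
                     multivariable: bool = True) -> ModelFit:
    """OLS of log10(peptide count) on log10(mass) [+ class and data-set factors].

    Returns coefficients, residuals and the hat-matrix diagonal (leverages),
    computed from the thin QR factorization of the design.  Raises on rank
    deficiency (naming the first aliased column) and when there are not
    enough observations to leave residual degrees of freedom.
    """
    if not observations:
        raise ValueError("no observations")
    X, names = _design_matrix(observations, multivariable)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} parameters, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"design is rank deficient; aliased column: {_first_aliased(X, names)}")
    y = np.log10([o.peptide_count for o in observations])
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    fitted = X @ beta
    resid = y - fitted
    leverages = np.sum(Q * Q, axis=1)
    return ModelFit(
        observations=list(observations),
        column_names=names,
        coefficients=beta,
        fitted=fitted,
        residuals=resid,
        leverages=leverages,
        df_resid=n - p,
    )


def studentized_residuals(fit: ModelFit) -> np.ndarray:
    """Externally studentized residuals t_i = e_i / (s_(i) * sqrt(1 - h_ii)).

    s_(i) is the residual scale of the fit *excluding* observation i, obtained
    by the closed-form downdate  s_(i)^2 = (SSE - e_i^2 / (1 - h_ii)) / (n - p - 1)
    rather than refitting.  Observations with leverage 1 get NaN (they carry
    no residual information).
    """
    if fit.df_resid < 2:
        raise ValueError("external studentization needs residual d.f. >= 2")
    e = fit.residuals
    h = fit.leverages
    n_minus_p = fit.df_resid
    t = np.full(len(e), np.nan)
    ok = h < 1.0 - 1e-12
    sse = fit.sse
    # an (effectively) perfect fit leaves every residual at zero; guard against
    # dividing machine noise by machine noise
    noise = (1e-12 * max(1.0, float(np.abs(fit.fitted).max()))) ** 2
    if sse <= noise * len(e):
        t[ok] = 0.0
        return t
    s2_loo = (sse - e[ok] ** 2 / (1.0 - h[ok])) / (n_minus_p - 1)
    s2_loo = np.maximum(s2_loo, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = e[ok] / np.sqrt(s2_loo * (1.0 - h[ok]))
    return t


def protein_sr(fit: ModelFit, ral: dict[str, float] | None = None
               ) -> list[AbundanceResult]:
    """Per-protein mean of the fit's studentized residuals, joined with RAL.

    ``ral`` maps locus tags to RAL values; proteins present there but absent
    from the fit (never detected) are reported with sr = None, mirroring the
    dash printed for undetected proteins.
    """
    t = studentized_residuals(fit)
    grouped: dict[str, list[float]] = {}
    for obs, ti in zip(fit.observations, t):
        grouped.setdefault(obs.locus_tag, []).append(float(ti))
    results = []
    loci = set(grouped) | set(ral or {})
    for locus in sorted(loci):
        tis = [x for x in grouped.get(locus, []) if not np.isnan(x)]
        sr = float(np.mean(tis)) if tis else None
        results.append(AbundanceResult(
            locus_tag=locus,
            ral=(ral or {}).get(locus, float("nan")),
            sr=sr,
            n_obs=len(grouped.get(locus, [])),
        ))
    return results


def abundance_report(results: list[AbundanceResult],
                     mass_kda: dict[str, float] | None = None,
                     total_peptides: dict[str, int] | None = None,
                     coverage_pct: dict[str, float] | None = None) -> pd.DataFrame:
    """Assemble the per-protein abundance table (Locus, kDa, Pep, Cov, RAL, SR)."""
    rows = []
    for r in results:
        rows.append({
            "locus_tag": r.locus_tag,
            "kda": (mass_kda or {}).get(r.locus_tag, ""),
            "total_peptides": (total_peptides or {}).get(r.locus_tag, 0),
            "coverage_pct": (coverage_pct or {}).get(r.locus_tag, ""),
            "ral": round(r.ral, 2),
            "sr": "" if r.sr is None else round(r.sr, 2),
        })
    return pd.DataFrame(rows, columns=["locus_tag", "kda", "total_peptides",
                                       "coverage_pct", "ral", "sr"])


def region_mean_ral(results: list[AbundanceResult], regions: dict[str, str]
                    ) -> pd.Series:
    """Arithmetic mean RAL per region (``regions`` maps locus tag -> region).

    Regions with no mapped proteins are absent from the result; callers can
    compare e.g. intact-prophage vs orphan categories with :func:`ral_ratio`.
    """
    by_region: dict[str, list[float]] = {}
    for r in results:
        if r.locus_tag not in regions:
            raise ValueError(f"no region mapping for {r.locus_tag}")
        by_region.setdefault(regions[r.locus_tag], []).append(r.ral)
    return pd.Series({reg: float(np.mean(v)) for reg, v in sorted(by_region.items())},
                     name="mean_ral")


def ral_ratio(means: pd.Series, numerator_regions: list[str],
              denominator_regions: list[str]) -> float:
    """Ratio of mean RAL between two region sets (e.g. intact vs orphan)."""
    num = means[means.index.isin(numerator_regions)].mean()
    den = means[means.index.isin(denominator_regions)].mean()
    return float(num / den)
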