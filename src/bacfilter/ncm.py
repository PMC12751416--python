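"""Sloan's neutral community model (NCM): fit, prediction band, classes.

Sloan's model predicts the detection frequency of a taxon in a set of
local communities purely from its mean relative abundance ``p`` in the
source community, a community size ``N`` (reads per sample are the usual
proxy) and a migration parameter ``m``: local relative abundances follow a
Beta(N*m*p, N*m*(1-p)) distribution, and the taxon is detected when its
abundance exceeds the detection limit ``d`` (default ln2/N; see
:class:`NeutralCommunityModel`), so

    predicted frequency = 1 - I_d(N*m*p, N*m*(1-p))

with ``I`` the regularised incomplete beta function. ``m`` is estimated by
bounded least squares of observed against predicted frequencies. Taxa
observed above the upper 95% bound of the prediction (Wilson score interval
at the realised number of samples) are classified ``above`` (advantaged:
more frequent than dispersal alone explains), below the lower bound
``below`` (disadvantaged), and otherwise ``neutral``.

The module follows the modelling-object convention: build a
:class:`NeutralCommunityModel` from data (or via ``from_counts``), call
``fit()`` and read estimates, diagnostics and the per-taxon table off the
returned :class:`NCMResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .io import CountMatrix

__all__ = [
    "ncm_predicted_freq",
    "wilson_interval",
    "prediction_band",
    "classify_taxa",
    "summarize_classes",
    "NeutralCommunityModel",
    "NCMResults",
]


def ncm_predicted_freq(p, m: float, N: float, d: float):
    """Neutral prediction of detection frequency; see the module docstring.

    ``p = 0`` returns 0 and ``p = 1`` returns 1 by limit convention.
    Strictly increasing in ``p`` (for fixed m, N, d) and in ``m`` for
    ``p > d``.
    """
    if not 0 < m <= 1:
        raise ValueError(f"migration m must be in (0, 1], got {m}")
    if not N >= 2:
        raise ValueError(f"community size N must be >= 2, got {N}")
    if not 0 < d < 1:
        raise ValueError(f"detection limit d must be in (0, 1), got {d}")
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValueError("mean relative abundance p must lie in [0, 1]")
    a = N * m * p_arr
    b = N * m * (1.0 - p_arr)
    with np.errstate(invalid="ignore"):
        freq = 1.0 - special.betainc(a, b, d)
    freq = np.where(p_arr == 0, 0.0, freq)
    freq = np.where(p_arr == 1, 1.0, freq)
    freq = np.clip(freq, 0.0, 1.0)
    return float(freq) if np.ndim(p) == 0 else freq


def wilson_interval(p, n: int, level: float = 0.95):
    """Wilson score interval for a proportion ``p`` observed over ``n`` trials."""
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if not n >= 2:
        raise ValueError("need n >= 2 samples")
    p_arr = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    z = float(special.ndtri(1.0 - (1.0 - level) / 2.0))
    denom = 1.0 + z**2 / n
    centre = (p_arr + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p_arr * (1 - p_arr) / n + z**2 / (4 * n**2))
    lower = np.clip(centre - half, 0.0, 1.0)
    upper = np.clip(centre + half, 0.0, 1.0)
    if np.ndim(p) == 0:
        return float(lower), float(upper)
    return lower, upper


def prediction_band(predicted, n_samples: int, level: float = 0.95):
    """95% (by default) Wilson band around predicted detection frequencies."""
    return wilson_interval(predicted, n_samples, level)


def classify_taxa(observed, lower, upper) -> np.ndarray:
    """'above' / 'neutral' / 'below' per taxon; on-bound observations are neutral."""
    observed = np.asarray(observed, dtype=float)
    out = np.full(observed.shape, "neutral", dtype=object)
    out[observed > np.asarray(upper)] = "above"
    out[observed < np.asarray(lower)] = "below"
    return out


def summarize_classes(labels: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Contingency of NCM class x taxon group with within-group percentages."""
    if set(labels.index) != set(groups.index):
        only_l = set(labels.index) - set(groups.index)
        only_g = set(groups.index) - set(labels.index)
        raise ValueError(
            f"label/group taxon sets differ (labels only: {len(only_l)}, "
            f"groups only: {len(only_g)})"
        )
    df = pd.DataFrame({"label": labels, "group": groups.reindex(labels.index)})
    counts = df.groupby(["group", "label"]).size().unstack("label", fill_value=0)
    for cls in ("above", "neutral", "below"):
        if cls not in counts.columns:
            counts[cls] = 0
    counts = counts[[c for c in ("above", "neutral", "below") if c in counts.columns]
                    + [c for c in counts.columns if c not in ("above", "neutral", "below")]]
    total = counts.sum(axis=1)
    pct = counts.div(total, axis=0) * 100.0
    pct.columns = [f"{c}_pct" for c in pct.columns]
    out = pd.concat([counts, pct], axis=1)
    out["n"] = total
    return out


@dataclass(frozen=True)
class NCMResults:
    """Fitted NCM: migration estimate, fit quality and per-taxon classes.

    ``table`` is indexed by taxon id with columns ``p`` (mean relative
    abundance), ``observed``, ``predicted``, ``lower``, ``upper`` and
    ``ncm_class`` ('above'/'neutral'/'below', or 'not_evaluated' for taxa
    excluded from the fit).
    """

    m: float
    m_stderr: float
    r_squared: float
    N: float
    d: float
    n_samples: int
    level: float
    table: pd.DataFrame
    n_fitted: int

    @property
    def class_counts(self) -> pd.Series:
        return self.table["ncm_class"].value_counts()

    def summary(self) -> str:
        cc = self.class_counts
        lines = [
            "Sloan neutral community model fit",
            "=" * 44,
            f"{'taxa (fitted/total)':<28}{self.n_fitted}/{len(self.table)}",
            f"{'samples':<28}{self.n_samples}",
            f"{'community size N':<28}{self.N:g}",
            f"{'detection limit d':<28}{self.d:.3e}",
            f"{'migration m':<28}{self.m:.4f} (SE {self.m_stderr:.4f})",
            f"{'R-squared':<28}{self.r_squared:.4f}",
            f"{'prediction band':<28}Wilson, level {self.level:g}",
            "-" * 44,
        ]
        for cls in ("above", "neutral", "below", "not_evaluated"):
            if cls in cc.index:
                n = int(cc[cls])
                lines.append(f"{cls:<28}{n} ({100 * n / len(self.table):.1f}%)")
        return "\n".join(lines)


class NeutralCommunityModel:
    """Sloan NCM over per-taxon (mean abundance, observed frequency) records.

    Parameters
    ----------
    p
        Mean relative abundance per taxon (source-community abundance when
        testing assembly from an external source, otherwise the dataset's
        own means).
    observed
        Observed detection frequency per taxon (proportion of samples with
        at least one read).
    N
        Community size; reads per sample are the standard proxy.
    n_samples
        Number of samples the frequencies were observed over (used for the
        prediction band).
    d
        Detection limit as a relative abundance. Defaults to ``ln2/N``, the
        abundance at which the probability of drawing at least one read in
        ``N`` (``1-(1-x)^N``) crosses one half — the step-function detection
        limit that best matches read-thinned detection. Pass ``1/N`` for the
        single-read convention.
    """

    #: deterministic multi-start list for the bounded 1-D fit
    _STARTS = (0.01, 0.1, 0.5)
    _BOUNDS = (1e-6, 1.0)

    def __init__(self, p, observed, N: float, n_samples: int, d: float | None = None,
                 taxon_ids=None):
        p = np.asarray(p, dtype=float)
        observed = np.asarray(observed, dtype=float)
        if p.shape != observed.shape:
            raise ValueError("p and observed must have equal length")
        if taxon_ids is None:
            taxon_ids = [f"taxon_{i}" for i in range(len(p))]
        self.p = p
        self.observed = observed
        self.N = float(N)
        self.n_samples = int(n_samples)
        self.d = float(d) if d is not None else float(np.log(2)) / float(N)
        self.taxon_ids = list(taxon_ids)
        self._fit_mask = (p > 0) & np.isfinite(observed)
        if self._fit_mask.sum() < 2:
            raise ValueError("need at least 2 taxa with p > 0 to fit the NCM")

    @classmethod
    def from_counts(
        cls,
        counts: CountMatrix,
        source_p: pd.Series | None = None,
        N: float | None = None,
        d: float | None = None,
        detection_threshold: int = 1,
    ) -> "NeutralCommunityModel":
        """Build the model from a count table.

        ``source_p`` optionally supplies external source-community mean
        abundances (e.g. the seeding influent); by default the table's own
        mean relative abundances are used. ``N`` defaults to the mean reads
        per sample.
        """
        rel = counts.relative_abundance()
        p = rel.mean(axis=1) if source_p is None else source_p.reindex(rel.index).fillna(0.0)
        observed = (counts.counts >= detection_threshold).mean(axis=1)
        if N is None:
            N = float(counts.column_sums().mean())
        return cls(
            p.to_numpy(float),
            observed.to_numpy(float),
            N=N,
            n_samples=len(counts.samples),
            d=d,
            taxon_ids=counts.taxa,
        )

    # -- fitting ---------------------------------------------------------
    def _residuals(self, m: float) -> np.ndarray:
        pred = ncm_predicted_freq(self.p[self._fit_mask], m, self.N, self.d)
        return pred - self.observed[self._fit_mask]

    def fit(self, level: float = 0.95) -> NCMResults:
        """Estimate ``m`` by bounded least squares (deterministic multi-start)."""
        obs = self.observed[self._fit_mask]
        sst = float(((obs - obs.mean()) ** 2).sum())
        if sst == 0:
            raise ValueError(
                "degenerate fit: all observed frequencies are equal (SST = 0)"
            )
        best = None
        for m0 in self._STARTS:
            res = optimize.least_squares(
                lambda v: self._residuals(v[0]),
                x0=[m0],
                bounds=([self._BOUNDS[0]], [self._BOUNDS[1]]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if best is None or res.cost < best.cost:
                best = res
        m_hat = float(best.x[0])
        sse = float((self._residuals(m_hat) ** 2).sum())
        r2 = 1.0 - sse / sst
        # 1-D Gauss-Newton standard error from the jacobian at the optimum
        jac = np.asarray(best.jac).ravel()
        jtj = float(jac @ jac)
        dof = max(int(self._fit_mask.sum()) - 1, 1)
        m_se = float(np.sqrt(sse / dof / jtj)) if jtj > 0 else float("nan")

        predicted = np.full(len(self.p), np.nan)
        predicted[self._fit_mask] = ncm_predicted_freq(
            self.p[self._fit_mask], m_hat, self.N, self.d
        )
        lower = np.full(len(self.p), np.nan)
        upper = np.full(len(self.p), np.nan)
        lo, hi = prediction_band(predicted[self._fit_mask], self.n_samples, level)
        lower[self._fit_mask] = lo
        upper[self._fit_mask] = hi
        classes = np.full(len(self.p), "not_evaluated", dtype=object)
        classes[self._fit_mask] = classify_taxa(
            self.observed[self._fit_mask], lo, hi
        )
        table = pd.DataFrame(
            {
                "p": self.p,
                "observed": self.observed,
                "predicted": predicted,
                "lower": lower,
                "upper": upper,
                "ncm_class": classes,
            },
            index=pd.Index(self.taxon_ids, name="taxon"),
        )
        return NCMResults(
            m=m_hat,
            m_stderr=m_se,
            r_squared=r2,
            N=self.N,
            d=self.d,
            n_samples=self.n_samples,
            level=level,
            table=table,
            n_fitted=int(self._fit_mask.sum()),
        )
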