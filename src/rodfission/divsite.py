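"""Relative division-site statistics and placement-model comparison.

Given two pole-to-septum distances d1 and d2 per dividing cell, the
mother-cell length is L = d1 + d2, the daughter length is min(d1, d2), and
the relative division site is S = daughter / mother, confined to (0, 0.5].
Because the measured poles are interchangeable, S is mirrored onto (0, 1)
(each value S contributes S and 1 - S with half weight) before density
estimation, so the estimated density is symmetric about 1/2 by
construction.

Cells are gated by mother length into short (L <= 5 µm), mid
(5 < L <= 8 µm) and long (L > 8 µm) classes; within a class S is assigned
to the nearest canonical fraction of that class (short {1/2}, mid
{1/2, 1/3}, long {1/2, 1/3, 1/4}).  Per-class mean S is the slope of the
daughter-vs-mother line through the origin.

Two placement models are contrasted on the mirrored data as equal-weight
Gaussian mixtures truncated to (0, 1):

* ``odd_fraction`` — septa at 1/2 and, with increasing length, the odd
  fractions 1/3 (2/3) and 1/4 (3/4);
* ``min_system`` — septa at the even fractions k/(2m) with k odd, as the
  Min (MinCDE) oscillator produces in elongated cells (1/4, 3/4; 1/6, 3/6,
  5/6; ...), with the number of potential sites m tied to the length class.

The ``DivisionSiteModel`` / ``DivisionSiteResults`` pair wraps these steps
in a fit-then-summarize workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from rodfission.errors import ConfigurationError, ValidationError

__all__ = [
    "MeasurementRecord",
    "DivisionRecord",
    "AnalysisConfig",
    "DivisionSiteModel",
    "DivisionSiteResults",
    "relative_division_site",
    "mirror_sites",
    "assign_fraction_class",
    "fit_class_lines",
    "estimate_density_modes",
    "canonical_fraction_sets",
    "compare_division_models",
]

#: canonical fraction labels used in reports
_FRACTION_LABELS = {0.5: "1/2", 1.0 / 3.0: "1/3", 0.25: "1/4"}


@dataclass(frozen=True)
class MeasurementRecord:
    """Two pole-to-division-site distances of one dividing cell, in µm."""

    cell_id: str
    replicate: str
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValidationError(
                f"cell {self.cell_id}: pole distances must be positive "
                f"(got {self.d1}, {self.d2})"
            )


@dataclass(frozen=True)
class DivisionRecord:
    """Derived per-cell division geometry."""

    cell_id: str
    L_mother: float
    L_daughter: float
    S: float
    fraction_class: str = "unassigned"
    replicate: str = "r1"


@dataclass
class AnalysisConfig:
    """Gating boundaries, canonical fraction sets and density settings."""

    class_boundaries: tuple[float, float] = (5.0, 8.0)
    allowed_fractions: dict = field(
        default_factory=lambda: {
            "short": (0.5,),
            "mid": (0.5, 1.0 / 3.0),
            "long": (0.5, 1.0 / 3.0, 0.25),
        }
    )
    kde_bandwidth: str | float = "silverman"
    mode_grid_step: float = 0.005
    mode_min_prominence: float = 0.1
    mode_prominence_window: float = 0.2
    histogram_bin_width: float = 0.02

    def __post_init__(self) -> None:
        b1, b2 = self.class_boundaries
        if not b1 < b2:
            raise ConfigurationError("class_boundaries must be strictly increasing")
        for cls, fr in self.allowed_fractions.items():
            if any(not (0.0 < f <= 0.5) for f in fr):
                raise ConfigurationError(
                    f"allowed fractions for {cls} must lie in (0, 0.5]"
                )

    def length_class(self, length: float) -> str:
        b1, b2 = self.class_boundaries
        if length <= b1:
            return "short"
        if length <= b2:
            return "mid"
        return "long"


def relative_division_site(rec: MeasurementRecord) -> DivisionRecord:
    """Compute mother length, daughter length and S from two pole distances.

    Mother length is d1 + d2; the daughter is the smaller of the two
    measurements; S = daughter / mother.  Symmetric in (d1, d2) and
    S in (0, 0.5] by construction.
    """
    if rec.d1 <= 0 or rec.d2 <= 0:
        raise ValidationError(f"cell {rec.cell_id}: non-positive pole distance")
    mother = rec.d1 + rec.d2
    daughter = min(rec.d1, rec.d2)
    return DivisionRecord(
        cell_id=rec.cell_id,
        L_mother=mother,
        L_daughter=daughter,
        S=daughter / mother,
        replicate=rec.replicate,
    )


def mirror_sites(records: Sequence[DivisionRecord]) -> pd.DataFrame:
    """Mirror S about 1/2 into a weighted sample on (0, 1).

    Each S < 0.5 contributes the points S and 1 - S with weight 0.5 each
    (either pole could host the measured daughter); S = 0.5 contributes a
    single point of weight 1.  Total weight equals the number of records,
    so densities keep their per-cell normalization.
    """
    rows = []
    for r in records:
        if not (0.0 < r.S <= 0.5):
            raise ValidationError(f"cell {r.cell_id}: S={r.S} outside (0, 0.5]")
        if r.S == 0.5:
            rows.append((r.cell_id, r.L_mother, 0.5, 1.0))
        else:
            rows.append((r.cell_id, r.L_mother, r.S, 0.5))
            rows.append((r.cell_id, r.L_mother, 1.0 - r.S, 0.5))
    return pd.DataFrame(rows, columns=["cell_id", "L_mother", "s", "weight"])


def assign_fraction_class(
    rec: DivisionRecord, config: Optional[AnalysisConfig] = None
) -> str:
    """Assign S to the nearest canonical fraction allowed for the length class.

    Ties go to the larger fraction (the more symmetric division).
    """
    config = config or AnalysisConfig()
    if not (0.0 < rec.S <= 0.5):
        raise ValidationError(f"cell {rec.cell_id}: S={rec.S} outside (0, 0.5]")
    allowed = config.allowed_fractions[config.length_class(rec.L_mother)]
    # nearest fraction; ties (to fp tolerance) go to the larger, more
    # symmetric one
    dists = {f: abs(rec.S - f) for f in allowed}
    dmin = min(dists.values())
    best = max(f for f, d in dists.items() if d <= dmin + 1e-12)
    return _FRACTION_LABELS.get(best, f"{best:g}")


def classify_records(
    records: Sequence[DivisionRecord], config: Optional[AnalysisConfig] = None
) -> list[DivisionRecord]:
    """Return records with ``fraction_class`` filled in."""
    config = config or AnalysisConfig()
    return [
        DivisionRecord(
            cell_id=r.cell_id, L_mother=r.L_mother, L_daughter=r.L_daughter,
            S=r.S, replicate=r.replicate,
            fraction_class=assign_fraction_class(r, config),
        )
        for r in records
    ]


def fit_class_lines(records: Sequence[DivisionRecord]) -> pd.DataFrame:
    """Per fraction class: mean S (slope of daughter = S̄ · mother), n, SD.

    Classes without records are omitted; records must carry an assigned
    ``fraction_class``.
    """
    if not records:
        raise ValidationError("fit_class_lines: no records")
    df = pd.DataFrame(
        {
            "fraction_class": [r.fraction_class for r in records],
            "S": [r.S for r in records],
        }
    )
    out = (
        df.groupby("fraction_class")["S"]
        .agg(slope="mean", n="size", sd=lambda s: float(np.std(s, ddof=0)))
        .reset_index()
    )
    return out.sort_values("slope", ascending=False, ignore_index=True)


def _weighted_kde(x: np.ndarray, w: np.ndarray, bandwidth: str | float):
    bw = bandwidth if isinstance(bandwidth, str) else float(bandwidth)
    return stats.gaussian_kde(x, bw_method=bw, weights=w)


def estimate_density_modes(
    mirrored: pd.DataFrame, config: Optional[AnalysisConfig] = None
) -> dict:
    """Weighted Gaussian KDE of the mirrored sample, its modes and histogram.

    Modes are local maxima of the density on a regular grid over [0, 1]
    whose peak prominence is at least ``mode_min_prominence`` times the
    global maximum.  Returns ``{"modes", "density", "histogram"}`` where
    ``density`` is an (x, density) table and ``histogram`` uses fixed-width
    bins of ``histogram_bin_width``.
    """
    config = config or AnalysisConfig()
    x = np.asarray(mirrored["s"], dtype=float)
    w = np.asarray(mirrored["weight"], dtype=float)
    if w.sum() < 10:
        raise ValidationError("estimate_density_modes: need at least 10 points")
    try:
        kde = _weighted_kde(x, w, config.kde_bandwidth)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "estimate_density_modes: degenerate (zero-variance) sample"
        ) from exc
    grid = np.arange(0.0, 1.0 + config.mode_grid_step / 2, config.mode_grid_step)
    dens = kde(grid)
    # prominence judged within a window of the canonical-fraction spacing
    # scale, so broad featureless humps are not reported as modes
    wlen = max(3, int(round(config.mode_prominence_window / config.mode_grid_step)))
    peaks, _ = signal.find_peaks(
        dens, prominence=config.mode_min_prominence * dens.max(), wlen=wlen
    )
    bins = np.arange(0.0, 1.0 + config.histogram_bin_width / 2,
                     config.histogram_bin_width)
    counts, edges = np.histogram(x, bins=bins, weights=w)
    return {
        "modes": [float(grid[p]) for p in peaks],
        "density": pd.DataFrame({"x": grid, "density": dens}),
        "histogram": pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "weight": counts}
        ),
    }


def canonical_fraction_sets(model: str, m_or_class) -> set[float]:
    """Canonical division-site fraction sets on (0, 1).

    ``min_system`` with m potential sites yields {k/(2m) : k odd, 1 <= k < 2m}
    (m=1 -> {1/2}; m=2 -> {1/4, 3/4}; m=3 -> {1/6, 3/6, 5/6}).
    ``odd_fraction`` per length class yields the mirrored odd-fraction sets
    short {1/2}, mid {1/3, 1/2, 2/3}, long {1/4, 1/3, 1/2, 2/3, 3/4}.
    """
    if model == "min_system":
        if isinstance(m_or_class, str):
            m = {"short": 1, "mid": 2, "long": 3}[m_or_class]
        else:
            m = int(m_or_class)
        if m < 1:
            raise ConfigurationError("min_system: m must be >= 1")
        return {k / (2.0 * m) for k in range(1, 2 * m, 2)}
    if model == "odd_fraction":
        sets = {
            "short": {0.5},
            "mid": {1.0 / 3.0, 0.5, 2.0 / 3.0},
            "long": {0.25, 1.0 / 3.0, 0.5, 2.0 / 3.0, 0.75},
        }
        key = m_or_class if isinstance(m_or_class, str) else \
            {1: "short", 2: "mid", 3: "long"}[int(m_or_class)]
        return set(sets[key])
    raise ConfigurationError(f"unknown placement model: {model!r}")


def _truncated_mixture_logpdf(
    x: np.ndarray, fractions: Sequence[float], sd: float
) -> np.ndarray:
    """Equal-weight Gaussian mixture truncated to (0, 1), renormalized."""
    fr = np.asarray(sorted(fractions), dtype=float)
    comps = stats.norm.pdf(x[:, None], loc=fr[None, :], scale=sd)
    mass = stats.norm.cdf(1.0, loc=fr, scale=sd) - stats.norm.cdf(0.0, loc=fr, scale=sd)
    dens = (comps / mass[None, :]).mean(axis=1)
    return np.log(np.maximum(dens, 1e-300))


def compare_division_models(
    mirrored: pd.DataFrame,
    models: Sequence[str] = ("odd_fraction", "min_system"),
    noise_sd_S: float = 0.02,
    config: Optional[AnalysisConfig] = None,
) -> dict:
    """Score placement models on mirrored data by truncated-mixture likelihood.

    Each record's length class selects the model's allowed fraction set;
    the weighted log-likelihood of the mirrored sample under the
    equal-weight truncated Gaussian mixture (component SD ``noise_sd_S``)
    is accumulated per model.  Reports log-likelihoods, BIC (k = number of
    distinct fractions the model used) and the winner by log-likelihood;
    exact ties are reported as ``"tie"``.
    """
    if noise_sd_S <= 0:
        raise ValidationError("noise_sd_S must be > 0")
    if len(models) < 2:
        raise ValidationError("need at least two models to compare")
    config = config or AnalysisConfig()

    x = np.asarray(mirrored["s"], dtype=float)
    w = np.asarray(mirrored["weight"], dtype=float)
    classes = np.array([config.length_class(L) for L in mirrored["L_mother"]])
    n_eff = float(w.sum())

    scores: dict[str, dict] = {}
    for model in models:
        ll = 0.0
        used: set[float] = set()
        for cls in np.unique(classes):
            sel = classes == cls
            fractions = canonical_fraction_sets(model, cls)
            used |= fractions
            ll += float(
                (w[sel] * _truncated_mixture_logpdf(x[sel], fractions, noise_sd_S)).sum()
            )
        k = len(used)
        scores[model] = {
            "log_likelihood": ll,
            "bic": k * math.log(n_eff) - 2.0 * ll,
            "n_fractions": k,
        }

    lls = {m: scores[m]["log_likelihood"] for m in models}
    best = max(lls, key=lls.get)
    winner = "tie" if sum(
        1 for v in lls.values() if v == lls[best]
    ) > 1 else best
    return {"models": scores, "winner": winner, "noise_sd_S": noise_sd_S}


# ---------------------------------------------------------------------------
# Model/Results wrappers


class DivisionSiteModel:
    """Division-site placement analysis of pole-distance measurements.

    Parameters
    ----------
    measurements : sequence of MeasurementRecord
        Two pole-to-septum distances per dividing cell.
    config : AnalysisConfig, optional
        Length-class boundaries, canonical fraction sets and density
        settings.

    ``fit()`` derives the per-cell statistic S, mirrors it, assigns
    fraction classes, fits per-class slopes, estimates density modes and
    contrasts the odd-fraction and Min-system placement models.
    """

    def __init__(self, measurements: Sequence[MeasurementRecord],
                 config: Optional[AnalysisConfig] = None):
        if not measurements:
            raise ValidationError("DivisionSiteModel: no measurements")
        self.measurements = list(measurements)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: Optional[AnalysisConfig] = None,
                       ) -> "DivisionSiteModel":
        """Build from a table with columns cell_id, replicate, d1_um, d2_um."""
        records = [
            MeasurementRecord(
                cell_id=str(r.cell_id),
                replicate=str(getattr(r, "replicate", "r1")),
                d1=float(r.d1_um), d2=float(r.d2_um),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(records, config=config)

    def fit(self, noise_sd_S: float = 0.02) -> "DivisionSiteResults":
        records = classify_records(
            [relative_division_site(m) for m in self.measurements], self.config
        )
        mirrored = mirror_sites(records)
        class_lines = fit_class_lines(records)
        density = estimate_density_modes(mirrored, self.config)
        comparison = compare_division_models(
            mirrored, ("odd_fraction", "min_system"), noise_sd_S, self.config
        )
        return DivisionSiteResults(
            model=self, records=records, mirrored=mirrored,
            class_lines=class_lines, modes=density["modes"],
            density=density["density"], histogram=density["histogram"],
            model_comparison=comparison,
        )


class DivisionSiteResults:
    """Fitted division-site statistics.

    Attributes
    ----------
    records : list of DivisionRecord
        Per-cell mother/daughter lengths, S and assigned fraction class.
    mirrored : DataFrame
        Weighted mirrored sample on (0, 1).
    class_lines : DataFrame
        Per-class slope (mean S), n and SD.
    modes : list of float
        KDE mode positions on (0, 1).
    model_comparison : dict
        Log-likelihoods, BIC and winner of odd-fraction vs Min-system.
    """

    def __init__(self, model, records, mirrored, class_lines, modes,
                 density, histogram, model_comparison):
        self.model = model
        self.records = records
        self.mirrored = mirrored
        self.class_lines = class_lines
        self.modes = modes
        self.density = density
        self.histogram = histogram
        self.model_comparison = model_comparison

    @property
    def n_cells(self) -> int:
        return len(self.records)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"cell_id": r.cell_id, "replicate": r.replicate,
                 "L_mother_um": r.L_mother, "L_daughter_um": r.L_daughter,
                 "S": r.S, "fraction_class": r.fraction_class}
                for r in self.records
            ]
        )

    def summary(self) -> str:
        lines = [
            "Division-site placement analysis",
            "=" * 48,
            f"n dividing cells: {self.n_cells}",
            "",
            "Per-class slopes (daughter = slope x mother):",
        ]
        for row in self.class_lines.itertuples(index=False):
            lines.append(
                f"  {row.fraction_class:>4}: slope={row.slope:.4f} "
                f"sd={row.sd:.4f} n={row.n}"
            )
        lines.append("")
        lines.append(
            "Density modes (mirrored S): "
            + ", ".join(f"{m:.3f}" for m in self.modes)
        )
        lines.append("")
        lines.append("Placement model comparison:")
        for name, sc in self.model_comparison["models"].items():
            lines.append(
                f"  {name:>13}: logL={sc['log_likelihood']:.2f} "
                f"BIC={sc['bic']:.2f} (k={sc['n_fractions']})"
            )
        lines.append(f"  winner: {self.model_comparison['winner']}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Histogram + density curve of the mirrored relative division site."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        widths = self.histogram["bin_right"] - self.histogram["bin_left"]
        total = self.mirrored["weight"].sum()
        ax.bar(self.histogram["bin_left"],
               self.histogram["weight"] / (total * widths),
               width=widths, align="edge", color="gold", alpha=0.7,
               label="histogram")
        ax.plot(self.density["x"], self.density["density"], color="green",
                label="density")
        ax.axvline(0.5, linestyle="--", color="gray")
        ax.set_xlabel("relative division site S (mirrored)")
        ax.set_ylabel("density")
        ax.legend()
        return ax
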