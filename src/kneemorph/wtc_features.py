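"""Area-normalized per-element statistics and the 48-parameter WT-C block.

Raw per-element analysis values cannot be compared across meshes because
element sizes differ; each value is first weighted by its element area,

    Y_i = A_i * X_i,

and summary statistics are taken over the normalized set.  Two tail
fractions then capture the morphometric hypotheses:

* ``w_percent`` — fraction of normalized wall-thickness values strictly
  below ``mu - alpha*sigma`` (thin regions indicate degradation);
* ``c_percent`` — fraction of normalized curvature values strictly above
  ``mu + alpha*sigma`` (rough regions form around defects);

with ``mu``/``sigma`` computed per individual analysis and ``alpha`` a
per-(compartment, analysis) weight chosen, cohort-wide, to maximize group
separation.  Per subject this yields 4 compartments x 2 analyses x
(mean, STD, Var, RMS, tail fraction, alpha) = 48 parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .group_stats import kruskal_wallis
from .morphometry import ElementField

log = logging.getLogger(__name__)

#: Table-style short names per compartment
COMPARTMENT_SHORT = {
    "fem_cart": "Fem",
    "pat_cart": "Pat",
    "tib_cart_lat": "Lat",
    "tib_cart_med": "Med",
}
ANALYSIS_SHORT = {"wall": "Wall", "curvature": "Curv"}

#: shipped alpha defaults: wall 0.5 (femoral, patellar, medial tibial) and
#: 0.3 (lateral tibial); curvature 5 for all cartilages
DEFAULT_ALPHAS = {
    ("fem_cart", "wall"): 0.5,
    ("pat_cart", "wall"): 0.5,
    ("tib_cart_med", "wall"): 0.5,
    ("tib_cart_lat", "wall"): 0.3,
    ("fem_cart", "curvature"): 5.0,
    ("pat_cart", "curvature"): 5.0,
    ("tib_cart_med", "curvature"): 5.0,
    ("tib_cart_lat", "curvature"): 5.0,
}

DEFAULT_ALPHA_GRID = (0.1, 0.2, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0)


@dataclass
class NormalizedField:
    """Area-weighted per-element values of one analysis on one compartment."""

    values: np.ndarray  # Y_i = A_i * X_i over valid elements only
    analysis_kind: str
    compartment: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    @property
    def n_elements(self) -> int:
        return int(len(self.values))


@dataclass(frozen=True)
class WTCParams:
    """Summary of one (compartment x analysis): moments, tail fraction, alpha."""

    mean: float
    std: float
    var: float
    rms: float
    percent_beyond: float
    alpha: float


def normalize_by_area(field: ElementField, compartment: str = "") -> NormalizedField:
    """Eq-style area weighting ``Y_i = A_i * X_i`` over valid elements only."""
    if field.n_valid == 0:
        raise ValueError("no valid elements to normalize")
    A = field.surface.face_areas[field.valid]
    X = field.values[field.valid]
    return NormalizedField(A * X, field.analysis_kind, compartment)


def summary_params(nf: NormalizedField) -> tuple[float, float, float, float]:
    """(mean, STD, VAR, RMS) of the normalized set.

    VAR/STD use the n-1 denominator; RMS = sqrt(mean of squares), so
    RMS^2 = mean^2 + VAR*(n-1)/n.
    """
    y = nf.values
    if len(y) < 2:
        raise ValueError("need at least 2 elements")
    mean = float(y.mean())
    var = float(y.var(ddof=1))
    return mean, float(np.sqrt(var)), var, float(np.sqrt(np.mean(y**2)))


def w_percent(nf: NormalizedField, alpha: float) -> float:
    """Fraction of values strictly below ``mu - alpha*sigma``.

    ``mu`` and ``sigma`` come from this same normalized set.  A constant
    field has sigma 0 and no element strictly below mu, hence 0.
    """
    return _tail_fraction(nf, alpha, side=-1)


def c_percent(nf: NormalizedField, alpha: float) -> float:
    """Fraction of values strictly above ``mu + alpha*sigma`` (mirror)."""
    return _tail_fraction(nf, alpha, side=+1)


def _tail_fraction(nf: NormalizedField, alpha: float, side: int) -> float:
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    y = nf.values
    if len(y) < 2:
        raise ValueError("need at least 2 elements")
    mu = y.mean()
    sigma = y.std(ddof=1)
    if side < 0:
        return float(np.mean(y < mu - alpha * sigma))
    return float(np.mean(y > mu + alpha * sigma))


def select_alpha(
    fields: Sequence[NormalizedField],
    labels: Sequence[str],
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    analysis_kind: str | None = None,
) -> float:
    """Grid search for the alpha maximizing group separation.

    For each candidate alpha the per-subject tail fractions are scored by
    the Kruskal-Wallis H across groups; the alpha with the largest H wins,
    ties broken toward the smaller alpha.  Deterministic.
    """
    if len(fields) != len(labels):
        raise ValueError("fields and labels length mismatch")
    grid = sorted(grid)
    if not grid:
        raise ValueError("alpha grid is empty")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    kind = analysis_kind or fields[0].analysis_kind
    tail = w_percent if kind == "wall" else c_percent

    best_alpha, best_h = grid[0], -np.inf
    any_variation = False
    for alpha in grid:
        vals = np.array([tail(f, alpha) for f in fields])
        if np.ptp(vals) == 0:
            continue
        any_variation = True
        h, _ = kruskal_wallis([vals[np.asarray(labels) == g] for g in groups])
        if h > best_h + 1e-12:
            best_h, best_alpha = h, alpha
    if not any_variation:
        log.warning("tail fractions identical at every alpha; returning %s", grid[0])
    return float(best_alpha)


def wtc_params(nf: NormalizedField, alpha: float) -> WTCParams:
    mean, std, var, rms = summary_params(nf)
    tail = w_percent(nf, alpha) if nf.analysis_kind == "wall" else c_percent(nf, alpha)
    return WTCParams(mean, std, var, rms, tail, float(alpha))


def wtc_column_names() -> list[str]:
    """The 48 column names, in fixed compartment-major order."""
    names = []
    for comp in ("fem_cart", "pat_cart", "tib_cart_lat", "tib_cart_med"):
        for kind in ("wall", "curvature"):
            prefix = COMPARTMENT_SHORT[comp] + ANALYSIS_SHORT[kind]
            tail = "BelowSTDWeight" if kind == "wall" else "AboveSTDWeight"
            names += [
                f"{prefix}Mean", f"{prefix}STD", f"{prefix}Var", f"{prefix}RMS",
                f"{prefix}{tail}", f"{prefix}STDWeight",
            ]
    return names


def assemble_wtc_block(
    analyses: dict[tuple[str, str], NormalizedField],
    alphas: dict[tuple[str, str], float] | None = None,
) -> dict[str, float]:
    """Assemble the 48 named WT-C values for one subject.

    ``analyses`` maps (compartment, analysis_kind) to the subject's
    normalized field; all 8 combinations must be present.  Alpha columns
    are shared across subjects processed with one configuration.
    """
    alphas = alphas or DEFAULT_ALPHAS
    expected = [
        (c, k)
        for c in ("fem_cart", "pat_cart", "tib_cart_lat", "tib_cart_med")
        for k in ("wall", "curvature")
    ]
    missing = [key for key in expected if key not in analyses]
    if missing:
        raise ValueError(f"missing analyses: {missing}")
    out: dict[str, float] = {}
    for comp, kind in expected:
        prefix = COMPARTMENT_SHORT[comp] + ANALYSIS_SHORT[kind]
        p = wtc_params(analyses[(comp, kind)], alphas[(comp, kind)])
        tail = "BelowSTDWeight" if kind == "wall" else "AboveSTDWeight"
        out[f"{prefix}Mean"] = p.mean
        out[f"{prefix}STD"] = p.std
        out[f"{prefix}Var"] = p.var
        out[f"{prefix}RMS"] = p.rms
        out[f"{prefix}{tail}"] = p.percent_beyond
        out[f"{prefix}STDWeight"] = p.alpha
    assert list(out) == wtc_column_names()
    return out


def unstable_features(table, threshold: float = 5.0) -> list[str]:
    """Columns whose cross-subject coefficient of variation exceeds the
    threshold (|sd / mean|); the configurable exclusion rule for WT-C
    features too unstable to classify on."""
    out = []
    for col in table.columns:
        vals = np.asarray(table[col], dtype=np.float64)
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        if mean == 0:
            if sd > 0:
                out.append(col)
            continue
        if abs(sd / mean) > threshold:
            out.append(col)
    return out


def save_alphas(alphas: dict[tuple[str, str], float], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({f"{c}|{k}": v for (c, k), v in alphas.items()}, indent=2)
    )


def load_alphas(path: str | Path) -> dict[tuple[str, str], float]:
    raw = json.loads(Path(path).read_text())
    return {tuple(key.split("|")): float(v) for key, v in raw.items()}
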