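"""Model assessment and selection across the nine-variant battery.

The protocol filters lexicographically: (1) randomness of the weighted
residuals (Wald-Wolfowitz runs test, aggregated as subjects passing out of
the total), (2) fraction of parameters estimated with CV below 100%
(rows within a tolerance band of the best survive), (3) lowest median BIC.
Between-meal differences in the absorption parameters are screened with
Kruskal-Wallis (and optionally paired Wilcoxon signed-rank) tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .map_estimation import FitConfig, FitResult, PriorSpec, fit_map
from .pk_models import ModelSpec
from .synthetic_data import InsulinDataset

logger = logging.getLogger("ipinsulin")

__all__ = [
    "RunsTestResult",
    "runs_test",
    "bic",
    "precision_fraction",
    "BatteryCell",
    "BatteryResult",
    "SelectionReport",
    "run_battery",
    "rank_models",
    "compare_meals",
]

_P_FLOOR = 1e-300  # reported instead of an exact zero p-value


# ---------------------------------------------------------------------------
# Runs test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunsTestResult:
    passed: bool
    p: float
    n_runs: int
    n_pos: int
    n_neg: int
    z: float | None = None
    method: str = "normal"


def _exact_runs_pmf(n_pos: int, n_neg: int) -> np.ndarray:
    """Exact distribution of the number of runs in a random arrangement of
    n_pos positive and n_neg negative signs; index = number of runs."""
    n = n_pos + n_neg
    total = comb(n, n_pos, exact=True)
    pmf = np.zeros(n + 1)
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * comb(n_pos - 1, k - 1, exact=True) * comb(n_neg - 1, k - 1, exact=True)
        else:
            k = (r - 1) // 2
            ways = comb(n_pos - 1, k, exact=True) * comb(n_neg - 1, k - 1, exact=True) + comb(
                n_pos - 1, k - 1, exact=True
            ) * comb(n_neg - 1, k, exact=True)
        pmf[r] = ways / total
    return pmf


def runs_test(
    residuals: Sequence[float],
    alpha: float = 0.05,
    method: str = "auto",
    min_n: int = 10,
) -> RunsTestResult:
    """Two-sided Wald-Wolfowitz runs test on the signs of a residual series.

    Exact zeros are dropped from the sign sequence.  ``method`` is
    "normal" (large-sample z approximation), "exact" (exact two-sided
    p from the runs distribution), or "auto" (exact below 20 signs).
    The series passes when p >= alpha: both too few runs (clustering,
    i.e. systematic model misfit) and too many (alternation) reject.
    """
    r = np.asarray(residuals, float)
    signs = np.sign(r[r != 0])
    n = len(signs)
    if n < min_n:
        raise ValueError(f"runs test needs >= {min_n} non-zero residuals, got {n}")
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return RunsTestResult(False, _P_FLOOR, 1, n_pos, n_neg, None, "degenerate")
    n_runs = int(1 + np.sum(signs[1:] != signs[:-1]))

    if method == "auto":
        method = "exact" if n < 20 else "normal"
    if method == "exact":
        pmf = _exact_runs_pmf(n_pos, n_neg)
        lo = float(pmf[: n_runs + 1].sum())
        hi = float(pmf[n_runs:].sum())
        p = min(1.0, 2.0 * min(lo, hi))
        z = None
    else:
        mu = 2.0 * n_pos * n_neg / n + 1.0
        var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
        z = (n_runs - mu) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    p = max(p, _P_FLOOR)
    return RunsTestResult(bool(p >= alpha), p, n_runs, n_pos, n_neg, z, method)


# ---------------------------------------------------------------------------
# BIC and precision
# ---------------------------------------------------------------------------


def bic(wrss: float, n: int, p: int) -> float:
    """BIC = WRSS + p*ln(n).  With known-SD Gaussian error, -2 ln L equals
    WRSS plus a data-only constant that cancels across models fitted to the
    same data, so it is dropped."""
    if n <= 0:
        raise ValueError("n must be positive")
    if p < 0 or n <= p:
        raise ValueError(f"need n > p >= 0, got n={n}, p={p}")
    return float(wrss + p * math.log(n))


def precision_fraction(fits: Iterable[FitResult]) -> float:
    """Percentage of estimated parameters with CV < 100%, pooled over the
    given fits; collapsed parameters are excluded from both counts, and a
    non-finite CV counts as imprecise."""
    total = 0
    precise = 0
    for fit in fits:
        for name in fit.free_names:
            cv = fit.cv.get(name, float("inf"))
            total += 1
            if np.isfinite(cv) and cv < 100.0:
                precise += 1
    if total == 0:
        raise ValueError("no estimated parameters in any fit")
    return 100.0 * precise / total


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------


@dataclass
class BatteryCell:
    subject: int
    spec: ModelSpec
    fit: FitResult | None = None
    runs: RunsTestResult | None = None
    bic: float | None = None
    error: str | None = None


@dataclass
class BatteryResult:
    cells: list[BatteryCell]
    alpha: float = 0.05

    def for_spec(self, spec: ModelSpec) -> list[BatteryCell]:
        return [c for c in self.cells if c.spec == spec]

    def summarize(self, precision_tol: float = 2.0) -> "SelectionReport":
        specs = sorted({str(c.spec) for c in self.cells})
        n_subjects = len({c.subject for c in self.cells})
        rows = []
        for s in specs:
            cells = self.for_spec(ModelSpec.from_string(s))
            ok = [c for c in cells if c.fit is not None]
            if not ok:
                logger.warning("all fits failed for model %s", s)
                continue
            rows.append(
                {
                    "model": s,
                    "runs_pass": sum(1 for c in ok if c.runs and c.runs.passed),
                    "n_subjects": n_subjects,
                    "precision_pct": precision_fraction([c.fit for c in ok]),
                    "median_bic": float(np.median([c.bic for c in ok])),
                    "n_params": int(np.median([c.fit.n_free for c in ok])),
                    "n_failed": len(cells) - len(ok),
                }
            )
        selected, trace = rank_models(rows, precision_tol=precision_tol)
        return SelectionReport(pd.DataFrame(rows), selected, trace)


@dataclass
class SelectionReport:
    """Per-model summary table plus the selected model and the elimination
    trace of the lexicographic filter."""

    table: pd.DataFrame
    selected: str
    trace: list[str]

    def to_markdown(self) -> str:
        lines = [
            "| Model | Residual independence | Parameters with CV < 100% | Median BIC |",
            "|-------|----------------------|---------------------------|------------|",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"| {r['model']} | {int(r['runs_pass'])}/{int(r['n_subjects'])} "
                f"| {r['precision_pct']:.0f}% | {r['median_bic']:.0f} |"
            )
        lines.append("")
        lines.append(f"Selected model: **{self.selected}**")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_battery(
    datasets: Sequence[InsulinDataset],
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
    specs: Sequence[ModelSpec] | None = None,
    alpha: float = 0.05,
) -> BatteryResult:
    """Fit every model variant to every subject and assess each fit.

    Individual fit failures are recorded in their cell rather than aborting
    the battery.  Deterministic for fixed config seeds.
    """
    if not datasets:
        raise ValueError("need at least one subject dataset")
    specs = list(specs) if specs is not None else ModelSpec.all_nine()
    config = config or FitConfig()
    cells: list[BatteryCell] = []
    for i, ds in enumerate(datasets):
        for spec in specs:
            cell = BatteryCell(subject=i, spec=spec)
            try:
                fit = fit_map(spec, ds, priors, config)
                cell.fit = fit
                cell.runs = runs_test(fit.residuals, alpha=alpha)
                cell.bic = bic(fit.wrss, fit.n_obs, fit.n_free)
            except Exception as exc:  # recorded, not dropped
                logger.warning("fit failed: subject %d model %s: %s", i, spec, exc)
                cell.error = str(exc)
            cells.append(cell)
    return BatteryResult(cells, alpha=alpha)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


def rank_models(
    rows: Sequence[dict] | pd.DataFrame,
    precision_tol: float = 2.0,
) -> tuple[str, list[str]]:
    """Lexicographic model selection over per-model summary rows.

    Each row needs ``model``, ``runs_pass``, ``precision_pct`` and
    ``median_bic`` (optionally ``n_params`` for the BIC tie-break).
    Stage 1 keeps the rows with the maximal runs-test pass count; stage 2
    keeps rows within ``precision_tol`` percentage points of the best
    precision among them; stage 3 picks the lowest median BIC, ties broken
    toward fewer parameters and otherwise reported as a tie.  Returns the
    selected model name and a human-readable elimination trace.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    rows = list(rows)
    if not rows:
        raise ValueError("rank_models needs at least one row")
    trace: list[str] = []

    best_pass = max(r["runs_pass"] for r in rows)
    stage1 = [r for r in rows if r["runs_pass"] == best_pass]
    out = sorted(r["model"] for r in rows if r not in stage1)
    trace.append(
        f"runs-test stage: kept {sorted(r['model'] for r in stage1)} with "
        f"pass count {best_pass}; eliminated {out}"
    )

    best_prec = max(r["precision_pct"] for r in stage1)
    stage2 = [r for r in stage1 if r["precision_pct"] >= best_prec - precision_tol]
    out = sorted(r["model"] for r in stage1 if r not in stage2)
    trace.append(
        f"precision stage: kept {sorted(r['model'] for r in stage2)} within "
        f"{precision_tol} points of best precision {best_prec:.0f}%; eliminated {out}"
    )

    best_bic = min(r["median_bic"] for r in stage2)
    stage3 = [r for r in stage2 if r["median_bic"] == best_bic]
    if len(stage3) > 1 and all("n_params" in r for r in stage3):
        fewest = min(r["n_params"] for r in stage3)
        stage3b = [r for r in stage3 if r["n_params"] == fewest]
        if len(stage3b) < len(stage3):
            trace.append(
                f"BIC tie at {best_bic:.4g} broken toward fewer parameters "
                f"({fewest}): kept {sorted(r['model'] for r in stage3b)}"
            )
            stage3 = stage3b
    if len(stage3) > 1:
        trace.append(
            f"BIC stage: tie among {sorted(r['model'] for r in stage3)} at {best_bic:.4g}"
        )
    selected = sorted(r["model"] for r in stage3)[0]
    trace.append(f"BIC stage: selected {selected} with median BIC {best_bic:.4g}")
    return str(selected), trace


# ---------------------------------------------------------------------------
# Between-meal comparison
# ---------------------------------------------------------------------------


def compare_meals(
    estimates: dict[str, np.ndarray],
    alpha: float = 0.05,
    pairwise: bool = False,
) -> dict[str, dict]:
    """Kruskal-Wallis comparison of per-meal parameter estimates.

    ``estimates`` maps a parameter name to an (n_subjects, n_meals) array.
    Optionally adds paired Wilcoxon signed-rank tests for each meal pair.
    Identical values across meals yield p = 1 (no detectable difference).
    """
    out: dict[str, dict] = {}
    for name, arr in estimates.items():
        arr = np.asarray(arr, float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError(f"{name}: need an (n_subjects, n_meals>=2) array")
        if arr.shape[0] < 3:
            raise ValueError(f"{name}: need >= 3 subjects")
        groups = [arr[:, j] for j in range(arr.shape[1])]
        if all(np.array_equal(groups[0], g) for g in groups[1:]):
            p = 1.0
        else:
            p = float(stats.kruskal(*groups).pvalue)
        entry = {"kruskal_p": p, "significant": bool(p < alpha)}
        if pairwise:
            pw = {}
            for a in range(arr.shape[1]):
                for b in range(a + 1, arr.shape[1]):
                    diff = groups[a] - groups[b]
                    if np.all(diff == 0):
                        pw[f"meal{a + 1}_vs_meal{b + 1}"] = 1.0
                    else:
                        pw[f"meal{a + 1}_vs_meal{b + 1}"] = float(
                            stats.wilcoxon(groups[a], groups[b]).pvalue
                        )
            entry["wilcoxon"] = pw
        out[name] = entry
    return out
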