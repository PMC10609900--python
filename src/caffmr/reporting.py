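"""Forest-plot output and human-readable result tables.

A forest table holds one row per exposure-outcome pair — point estimate,
confidence bounds, p — on the beta scale for continuous outcomes and the
odds-ratio scale for binary ones. Printed precision follows the field's
reporting style: betas and CI bounds to 3 decimals, odds ratios to 2,
p-values in scientific notation with 2 significant digits.

:func:`render_forest` draws the classic forest layout (point + whiskers
per row, null line at 0 or 1) with matplotlib and writes a JSON metadata
sidecar next to the image recording what was plotted, so figures can be
checked programmatically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .mr import MRResult

__all__ = ["ForestRow", "forest_table", "forest_rows_to_tsv", "render_forest"]


@dataclass(frozen=True)
class ForestRow:
    """One plotted interval of a forest plot."""

    exposure_label: str
    outcome_label: str
    k: int
    beta: float
    ci_low: float
    ci_high: float
    pvalue: float
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "odds_ratio"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValidationError(
                f"{self.exposure_label}/{self.outcome_label}: interval "
                f"[{self.ci_low}, {self.ci_high}] does not bracket {self.beta}"
            )

    @property
    def null_value(self) -> float:
        return 1.0 if self.scale == "odds_ratio" else 0.0

    def formatted(self) -> dict:
        """Render at printed precision (betas 3 dp, ORs 2 dp, p 2 sig figs)."""
        dp = 2 if self.scale == "odds_ratio" else 3
        return {
            "exposure": self.exposure_label,
            "outcome": self.outcome_label,
            "k": self.k,
            "scale": self.scale,
            "estimate": f"{self.beta:.{dp}f}",
            "ci": f"[{self.ci_low:.{dp}f}, {self.ci_high:.{dp}f}]",
            "pvalue": f"{self.pvalue:.1e}",
        }


def forest_table(
    results: list[tuple[str, str, MRResult]],
) -> list[ForestRow]:
    """Build forest rows from finalized results, one per exposure-outcome pair.

    Binary outcomes are rendered on the odds-ratio scale. Row order follows
    the input order (exposures then outcomes, as configured by the caller).
    """
    rows: list[ForestRow] = []
    for exposure_label, outcome_label, result in results:
        if result.ci_low is None or result.pvalue is None:
            raise ValidationError(
                f"{exposure_label}/{outcome_label}: result not finalized"
            )
        if result.trait_type == "binary":
            rows.append(
                ForestRow(
                    exposure_label=exposure_label,
                    outcome_label=outcome_label,
                    k=result.k,
                    beta=result.or_,
                    ci_low=result.or_ci_low,
                    ci_high=result.or_ci_high,
                    pvalue=result.pvalue,
                    scale="odds_ratio",
                )
            )
        else:
            rows.append(
                ForestRow(
                    exposure_label=exposure_label,
                    outcome_label=outcome_label,
                    k=result.k,
                    beta=result.beta,
                    ci_low=result.ci_low,
                    ci_high=result.ci_high,
                    pvalue=result.pvalue,
                    scale="beta",
                )
            )
    return rows


def forest_rows_to_tsv(rows: list[ForestRow], path) -> pd.DataFrame:
    """Write forest rows as TSV at printed precision; returns the frame."""
    df = pd.DataFrame([r.formatted() for r in rows])
    if df.empty:
        df = pd.DataFrame(
            columns=["exposure", "outcome", "k", "scale", "estimate", "ci", "pvalue"]
        )
    df.to_csv(path, sep="\t", index=False)
    return df


def render_forest(rows: list[ForestRow], path) -> Path:
    """Draw a forest plot; mixed scales are split into side-by-side facets.

    Writes the figure to ``path`` and a JSON sidecar (``<path>.meta.json``)
    recording the number of plotted intervals per facet and their scales.
    Layout is deterministic given the rows.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not rows:
        raise ValidationError("render_forest requires at least one row")

    scales = [s for s in ("beta", "odds_ratio") if any(r.scale == s for r in rows)]
    fig, axes = plt.subplots(
        1, len(scales), figsize=(4.5 * len(scales) + 2.5, 0.45 * len(rows) + 1.5),
        squeeze=False,
    )
    meta: dict = {"facets": [], "n_intervals": len(rows)}
    for ax, scale in zip(axes[0], scales):
        facet = [r for r in rows if r.scale == scale]
        ys = range(len(facet), 0, -1)
        for y, r in zip(ys, facet):
            ax.plot([r.ci_low, r.ci_high], [y, y], color="black", lw=1.2)
            ax.plot([r.beta], [y], marker="s", color="black", ms=5)
        null = facet[0].null_value
        ax.axvline(null, color="grey", ls="--", lw=0.8)
        ax.set_yticks(list(ys))
        ax.set_yticklabels([f"{r.exposure_label} → {r.outcome_label}" for r in facet])
        ax.set_xlabel("odds ratio" if scale == "odds_ratio" else "beta (95% CI)")
        ax.set_ylim(0.5, len(facet) + 0.5)
        meta["facets"].append(
            {"scale": scale, "n_intervals": len(facet), "null_line": null}
        )
    fig.suptitle("Two-sample MR estimates")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path
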