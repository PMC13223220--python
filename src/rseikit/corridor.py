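"""Belt-gradient and section-comparison statistics on RSEI stacks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rseikit.composite import CLASS_NAMES
from rseikit.raster import check_congruent
from rseikit.synthetic import SECTIONS, CorridorScene


@dataclass
class SectionSummary:
    """Per-section long-term statistics and the cross-section contrast."""

    table: pd.DataFrame  # index: section; columns: mean, sd, cv_percent, ...
    difference: float  # south minus north long-term mean
    welch_t: float
    welch_p: float
    class_fractions: pd.DataFrame  # section x class, percent


def belt_statistics(
    rsei_layers: dict[int, np.ndarray] | np.ndarray,
    corridor: CorridorScene,
    cumulative: bool = False,
) -> pd.DataFrame:
    """Mean/sd/n of RSEI per section x distance belt (x year if a dict).

    With ``cumulative`` each belt b aggregates belts 1..b ("within
    2000 m" style) instead of the default per-belt rings.  Empty belts
    appear with n=0 and null statistics.
    """
    if isinstance(rsei_layers, np.ndarray):
        rsei_layers = {-1: rsei_layers}
    rows = []
    for year, layer in rsei_layers.items():
        check_congruent(layer, corridor.belt_id)
        for section in SECTIONS:
            sec_mask = corridor.section_mask(section)
            for belt in range(1, corridor.n_belts + 1):
                in_belt = corridor.belt_id <= belt if cumulative else corridor.belt_id == belt
                mask = sec_mask & in_belt & np.isfinite(layer)
                vals = layer[mask]
                rows.append(
                    {
                        "year": year,
                        "section": section,
                        "belt": belt,
                        "mean": vals.mean() if vals.size else np.nan,
                        "sd": vals.std(ddof=1) if vals.size > 1 else (0.0 if vals.size else np.nan),
                        "n": int(vals.size),
                    }
                )
    df = pd.DataFrame(rows)
    if set(df["year"]) == {-1}:
        df = df.drop(columns="year")
    return df


def annual_section_means(
    rsei_by_year: dict[int, np.ndarray], corridor: CorridorScene
) -> pd.DataFrame:
    """Mean RSEI over buffered valid pixels, per section and year."""
    rows = []
    for year, layer in sorted(rsei_by_year.items()):
        check_congruent(layer, corridor.belt_id)
        for section in SECTIONS:
            mask = corridor.section_mask(section) & np.isfinite(layer)
            if not mask.any():
                raise ValueError(f"section {section!r} has no valid buffered pixels in {year}")
            rows.append({"year": year, "section": section, "mean": float(layer[mask].mean())})
    return pd.DataFrame(rows)


def section_summary(
    rsei_by_year: dict[int, np.ndarray],
    corridor: CorridorScene,
    class_by_year: dict[int, np.ndarray] | None = None,
    pooled: bool = False,
) -> SectionSummary:
    """Long-term section statistics and the north-south contrast.

    The long-term mean and sd are, by default, the mean and sd of the
    annual section means (the interannual view); ``pooled`` switches to
    per-pixel pooling across all years.  The significance of the
    south-north difference uses Welch's two-sample t on annual means.
    """
    if len(rsei_by_year) < 2:
        raise ValueError("section_summary needs at least 2 years")
    annual = annual_section_means(rsei_by_year, corridor)
    per_section = {}
    for section in SECTIONS:
        if pooled:
            vals = np.concatenate(
                [
                    layer[corridor.section_mask(section) & np.isfinite(layer)]
                    for layer in rsei_by_year.values()
                ]
            )
        else:
            vals = annual.loc[annual["section"] == section, "mean"].to_numpy()
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        per_section[section] = {
            "mean": mean,
            "sd": sd,
            "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan,
            "n_years": len(rsei_by_year),
        }
    table = pd.DataFrame(per_section).T

    north = annual.loc[annual["section"] == "north", "mean"].to_numpy()
    south = annual.loc[annual["section"] == "south", "mean"].to_numpy()
    t_stat, p_val = stats.ttest_ind(south, north, equal_var=False)

    if class_by_year is None:
        fractions = pd.DataFrame(index=list(SECTIONS), columns=list(CLASS_NAMES), dtype=float)
    else:
        frac_rows = {}
        for section in SECTIONS:
            sec_mask = corridor.section_mask(section)
            counts = np.zeros(len(CLASS_NAMES))
            for layer in class_by_year.values():
                vals = layer[sec_mask & (layer >= 0)]
                counts += np.bincount(vals, minlength=len(CLASS_NAMES))
            frac_rows[section] = 100.0 * counts / counts.sum()
        fractions = pd.DataFrame(frac_rows, index=list(CLASS_NAMES)).T

    return SectionSummary(
        table=table,
        difference=float(south.mean() - north.mean()),
        welch_t=float(t_stat),
        welch_p=float(p_val),
        class_fractions=fractions,
    )


def area_fractions(class_layer: np.ndarray, corridor: CorridorScene) -> pd.DataFrame:
    """Percent of buffered valid pixels in each quality class, per section."""
    check_congruent(class_layer, corridor.belt_id)
    rows = {}
    for section in SECTIONS:
        mask = corridor.section_mask(section) & (class_layer >= 0)
        if not mask.any():
            raise ValueError(f"section {section!r} has no valid classified pixels")
        counts = np.bincount(class_layer[mask], minlength=len(CLASS_NAMES))
        rows[section] = 100.0 * counts / counts.sum()
    return pd.DataFrame(rows, index=list(CLASS_NAMES)).T
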