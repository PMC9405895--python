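"""Per-acquisition processing and group-level analysis.

`run_subject` executes the full chain on one acquisition — segment the
vessel, propagate masks, background-correct, convert to velocity, unwrap,
form the flow-rate series, align the physio record, estimate rates, and run
the spectral analysis — returning one flat result row.  `run_group` applies
the Friedman / Conover / FDR machinery to every index across breathing
modes and emits tidy comparison and descriptive tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import physio as phys
from .flow import flow_rate_series
from .io import PCSeries, PhysioRecord
from .segmentation import (
    SeedBox,
    mask_area,
    propagate_masks,
    segment_nfa,
    segment_vessel,
    select_reference_frame,
)
from .spectral import spectral_summary
from .stats import GroupTable, fdr_adjust, friedman_test, durbin_conover_pairs, median_range

__all__ = ["RunConfig", "PipelineError", "run_subject", "run_group"]

log = logging.getLogger(__name__)

RESULT_FIELDS = [
    "mean_flow",
    "variance",
    "area_ref",
    "area_mean",
    "hf_peak",
    "vhf_peak",
    "br_hz",
    "hr_hz",
    "auc_resp",
    "auc_card",
    "nauc_resp",
    "nauc_card",
    "ratio",
]

#: indices compared across breathing modes, mirroring the group tables
GROUP_INDICES = ["mean_flow", "variance", "area_mean", "ratio", "nauc_resp", "nauc_card"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Options controlling one pipeline run (all design decisions surfaced)."""

    propagation_mode: str = "copy"  # or "reseed"
    nfa_inner: int = 2
    nfa_outer: int = 5
    band_mode: str = "fixed"  # or "peak-relative"
    guidance: bool = True  # shrink peak windows around measured rates
    venous_sign: bool = True
    unwrap: bool = True
    detrend_order: int = 4
    fdr_scope: str = "per-index"  # or "global"
    seed: int = 0

    def __post_init__(self):
        if self.propagation_mode not in ("copy", "reseed"):
            raise ValueError("propagation_mode must be copy|reseed")
        if self.band_mode not in ("fixed", "peak-relative"):
            raise ValueError("band_mode must be fixed|peak-relative")
        if self.fdr_scope not in ("per-index", "global"):
            raise ValueError("fdr_scope must be per-index|global")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


def run_subject(
    series: PCSeries,
    box: SeedBox,
    config: RunConfig = RunConfig(),
    physio: PhysioRecord | None = None,
    subject: str = "S01",
) -> dict:
    """Process one acquisition end to end; returns a flat result row.

    A missing physio record degrades gracefully: the spectral peaks are then
    searched unguided and br_hz / hr_hz are reported as NaN.
    """
    cfg = config
    ref = _stage("select_reference_frame")(select_reference_frame)(series, box)
    ref_frame_mag = series.magnitude[ref]
    ref_mask = _stage("segment_vessel")(segment_vessel)(ref_frame_mag, box)
    nfa = _stage("segment_nfa")(segment_nfa)(
        ref_frame_mag, ref_mask, box, inner=cfg.nfa_inner, outer=cfg.nfa_outer
    )
    roi = _stage("propagate_masks")(propagate_masks)(
        series, ref_mask, ref, mode=cfg.propagation_mode, box=box, nfa=nfa
    )
    flow = _stage("flow_rate_series")(flow_rate_series)(
        series, roi, venous_sign=cfg.venous_sign, unwrap=cfg.unwrap
    )

    br = hr = math.nan
    if physio is not None:
        aligned = _stage("align_physio")(phys.align_physio)(physio, series)
        br = _stage("mean_rate")(phys.mean_rate)(aligned.resp, aligned.fs, "resp").rate
        hr = _stage("mean_rate")(phys.mean_rate)(aligned.pulse, aligned.fs, "pulse").rate

    areas = [mask_area(roi.masks[t], series.meta.pixel_spacing) for t in range(series.n_frames)]
    summ = _stage("spectral_summary")(spectral_summary)(
        flow,
        resp_rate=br if (cfg.guidance and physio is not None) else None,
        card_rate=hr if (cfg.guidance and physio is not None) else None,
        detrend_order=cfg.detrend_order,
        band_mode=cfg.band_mode,
        area_mean=float(np.mean(areas)),
    )
    return {
        "subject": subject,
        "vessel": series.meta.vessel_label,
        "mode": series.meta.breathing_mode,
        "mean_flow": summ.mean_flow,
        "variance": summ.variance,
        "area_ref": mask_area(roi.masks[ref], series.meta.pixel_spacing),
        "area_mean": summ.area_mean,
        "hf_peak": summ.hf_peak,
        "vhf_peak": summ.vhf_peak,
        "br_hz": br,
        "hr_hz": hr,
        "auc_resp": summ.auc_resp,
        "auc_card": summ.auc_card,
        "nauc_resp": summ.nauc_resp,
        "nauc_card": summ.nauc_card,
        "ratio": summ.ratio_resp_card,
    }


def _complete_pivot(df: pd.DataFrame, index_name: str, modes) -> GroupTable | None:
    pivot = df.pivot_table(index="subject", columns="mode", values=index_name, aggfunc="first")
    missing = pivot.index[pivot[list(modes)].isna().any(axis=1)].tolist()
    if missing:
        log.warning("index %s: excluding incomplete subjects %s", index_name, missing)
        pivot = pivot.drop(index=missing)
    if len(pivot) < 2:
        return None
    return GroupTable(
        values=pivot[list(modes)].to_numpy(),
        condition_labels=tuple(modes),
        subject_ids=tuple(pivot.index),
    )


def run_group(
    results: pd.DataFrame,
    config: RunConfig = RunConfig(),
    indices: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group comparisons across breathing modes, per vessel and index.

    Returns ``(stats, descriptives)``: one stats row per (vessel, index,
    pairwise comparison) with the Friedman omnibus p, the raw Conover p and
    its FDR-adjusted value; one descriptive row per (vessel, index, mode)
    as median [min, max].  FDR families follow ``config.fdr_scope``:
    per-index (each index's pairwise set, the default) or global.
    """
    log.info(
        "group analysis: band_mode=%s fdr_scope=%s propagation=%s",
        config.band_mode,
        config.fdr_scope,
        config.propagation_mode,
    )
    if indices is None:
        indices = [c for c in GROUP_INDICES if c in results.columns]
    modes = [m for m in ("F", "PN", "PD") if m in set(results["mode"])]
    stat_rows, desc_rows = [], []
    for vessel, sub in results.groupby("vessel", sort=True):
        for index_name in indices:
            table = _complete_pivot(sub, index_name, modes)
            if table is None:
                log.warning("index %s vessel %s: not enough complete blocks", index_name, vessel)
                continue
            fr = friedman_test(table)
            for pair, p_raw in durbin_conover_pairs(table):
                stat_rows.append(
                    {
                        "vessel": vessel,
                        "index": index_name,
                        "comparison": f"{pair[0]} vs {pair[1]}",
                        "friedman_stat": fr.statistic,
                        "friedman_p": fr.p_value,
                        "p_raw": p_raw,
                    }
                )
            for j, mode in enumerate(modes):
                med, lo, hi = median_range(table.values[:, j])
                desc_rows.append(
                    {
                        "vessel": vessel,
                        "index": index_name,
                        "mode": mode,
                        "median": med,
                        "min": lo,
                        "max": hi,
                        "n": table.n,
                    }
                )
    stats_df = pd.DataFrame(stat_rows)
    if not stats_df.empty:
        if config.fdr_scope == "global":
            stats_df["p_fdr"] = fdr_adjust(stats_df["p_raw"].to_numpy())
        else:
            stats_df["p_fdr"] = np.nan
            for _, grp in stats_df.groupby(["vessel", "index"]):
                stats_df.loc[grp.index, "p_fdr"] = fdr_adjust(grp["p_raw"].to_numpy())
    return stats_df, pd.DataFrame(desc_rows)
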