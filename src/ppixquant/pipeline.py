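"""End-to-end helpers: simulate, quantify and summarise whole studies."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .quantify import ROI, extract_timeseries, tumor_background_ratio
from .scene import StudyDesign, SimulatedStudy, generate_series


def study_rois(study: SimulatedStudy) -> list[ROI]:
    return [ROI(id=r["id"], center=(r["row"], r["col"]), radius=r["radius"],
                label=r["label"]) for r in study.rois]


def quantify_study(study: SimulatedStudy, camera: str = "external") -> pd.DataFrame:
    """ROI statistics for every specimen of one camera's stacks.

    Returns the long table ``specimen, roi, label, time_min, mean, sd``.
    """
    rois = study_rois(study)
    times = study.design.times_min
    out = []
    for s, stack in enumerate(study.frames[camera]):
        ts = extract_timeseries(stack, rois, times)
        df = ts.table.copy()
        df.insert(0, "specimen", s)
        out.append(df)
    return pd.concat(out, ignore_index=True)


def per_specimen_ratios(quant: pd.DataFrame, numerator: str = "tumor",
                        denominator: str = "brain") -> pd.DataFrame:
    """Per-specimen, per-time ratio of two labelled ROI means."""
    num = quant[quant["label"] == numerator].set_index(["specimen", "time_min"])["mean"]
    den = quant[quant["label"] == denominator].set_index(["specimen", "time_min"])["mean"]
    ratio = (num / den).rename("ratio").reset_index()
    return ratio


def simulate_and_ratio_summary(design: StudyDesign, n_studies: int, seed: int,
                               camera: str = "external") -> pd.DataFrame:
    """Run ``n_studies`` independent replicate studies and pool per-specimen
    tumor/brain and brain/dark-floor ratios.

    Returns a long table: ``study, specimen, time_min, tbr, brain_to_dark``.
    """
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(n_studies) % (2**31)
    for i, s in enumerate(seeds):
        d = replace(design, seed=int(s))
        study = generate_series(d)
        quant = quantify_study(study, camera=camera)
        tbr = per_specimen_ratios(quant, "tumor", "brain")
        b2d = per_specimen_ratios(quant, "brain", "dark_background")
        merged = tbr.merge(b2d, on=["specimen", "time_min"],
                           suffixes=("_tbr", "_b2d"))
        merged.insert(0, "study", i)
        rows.append(merged.rename(columns={"ratio_tbr": "tbr",
                                           "ratio_b2d": "brain_to_dark"}))
    return pd.concat(rows, ignore_index=True)
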