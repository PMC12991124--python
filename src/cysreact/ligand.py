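"""ATP add-back ligand sensitivity and covalent-inhibitor engagement.

The add-back experiment treats split lysates with ATP before probe labeling;
a drop in labeling at a cysteine marks it as nucleotide-proximal
("occluded"). Deltas (log2 treated/control) are computed within each plex
between paired channels — the add-back is a paired lysate-level perturbation,
so pairing removes channel loading effects — then aggregated over donors by
the median. The cross-state rule flags sites whose ATP response differs
between two cell states by at least the fold-change threshold (algebraically
identical to a "ratio of fold changes" cutoff).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import PeptideQuantRecord, PlexLayout, ProteinDatabase
from .quant import _map_sites, records_to_long

logger = logging.getLogger(__name__)


class LigandError(ValueError):
    """Invalid input to ligand-sensitivity analysis."""


def paired_deltas(
    records: Sequence[PeptideQuantRecord],
    layouts: Sequence[PlexLayout],
    treatment: str = "ATP",
    control_treatment: str = "none",
) -> pd.DataFrame:
    """Within-plex paired log2(treated/control) deltas per peptide and state.

    Channels are paired by replicate number within (plex, state); the
    per-record state delta is the median over replicate pairs. States missing
    either arm in the layout are skipped with a warning.
    """
    long = records_to_long(records, layouts)
    if len(long) == 0:
        return pd.DataFrame(
            columns=["plex", "accession", "sequence", "offsets", "state", "delta_log2"]
        )
    for layout in layouts:
        for state in layout.conditions:
            has_t = bool(layout.channels_for(state, treatment))
            has_c = bool(layout.channels_for(state, control_treatment))
            if has_t != has_c:
                logger.warning(
                    "plex %s state %s: missing %s arm; state skipped",
                    layout.plex_id,
                    state,
                    control_treatment if has_t else treatment,
                )
    long = long[long["intensity"] > 0].copy()
    long["log2i"] = np.log2(long["intensity"])
    key = ["plex", "accession", "sequence", "offsets", "condition", "replicate"]
    ctrl = long[long["treatment"] == control_treatment][key + ["log2i"]].rename(
        columns={"log2i": "log2_control"}
    )
    trt = long[long["treatment"] == treatment][key + ["log2i"]].rename(
        columns={"log2i": "log2_treated"}
    )
    pairs = ctrl.merge(trt, on=key, how="inner")
    if len(pairs) == 0:
        return pd.DataFrame(
            columns=["plex", "accession", "sequence", "offsets", "state", "delta_log2"]
        )
    pairs["delta"] = pairs["log2_treated"] - pairs["log2_control"]
    out = (
        pairs.groupby(["plex", "accession", "sequence", "offsets", "condition"], sort=False)[
            "delta"
        ]
        .median()
        .rename("delta_log2")
        .reset_index()
        .rename(columns={"condition": "state"})
    )
    return out.sort_values(
        ["plex", "accession", "sequence", "offsets", "state"], kind="mergesort"
    ).reset_index(drop=True)


def call_ligand_sensitivity(
    records: Sequence[PeptideQuantRecord],
    layouts: Sequence[PlexLayout],
    database: ProteinDatabase,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-site ATP-sensitivity calls from an add-back experiment.

    Returns one row per (site, state) with the donor-median paired delta,
    the ``sensitive`` flag (|delta| >= log2 threshold) and the direction
    (``decreased`` = reduced probe labeling upon ATP, the occlusion
    signature; increases are reported too).
    """
    if threshold <= 1:
        raise LigandError(f"threshold must be > 1, got {threshold}")
    deltas = paired_deltas(records, layouts)
    if len(deltas) == 0:
        return pd.DataFrame(
            columns=[
                "site_id", "accession", "composite", "state", "delta_log2",
                "n_donors", "sensitive", "direction",
            ]
        )
    log_thr = math.log2(threshold)
    mapped = _map_sites(deltas.rename(columns={"delta_log2": "log2_ratio"}), database)
    site_plex = (
        mapped.groupby(["site_id", "accession", "composite", "state", "plex"], sort=False)[
            "log2_ratio"
        ]
        .median()
        .reset_index()
    )
    out = (
        site_plex.groupby(["site_id", "accession", "composite", "state"], sort=False)
        .agg(delta_log2=("log2_ratio", "median"), n_donors=("plex", "nunique"))
        .reset_index()
    )
    out["sensitive"] = np.abs(out["delta_log2"]) >= log_thr
    out["direction"] = np.where(out["delta_log2"] < 0, "decreased", "increased")
    out.loc[out["delta_log2"] == 0, "direction"] = ""
    return out.sort_values(["site_id", "state"], kind="mergesort").reset_index(drop=True)


def cross_state_sensitivity(
    calls: pd.DataFrame,
    state_x: str = "D8C",
    state_y: str = "D2",
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Flag sites whose ATP response differs between two states.

    The flag fires when |delta(state_x) - delta(state_y)| >= log2(threshold),
    i.e. when the ratio of the two ATP fold changes exceeds the threshold.
    Only sites quantified in both states are considered.
    """
    if threshold <= 1:
        raise LigandError(f"threshold must be > 1, got {threshold}")
    for state in (state_x, state_y):
        if state not in set(calls["state"]):
            raise LigandError(f"state {state!r} absent from ligand calls")
    log_thr = math.log2(threshold)
    x = calls[calls["state"] == state_x][["site_id", "accession", "delta_log2"]].rename(
        columns={"delta_log2": "delta_x"}
    )
    y = calls[calls["state"] == state_y][["site_id", "delta_log2"]].rename(
        columns={"delta_log2": "delta_y"}
    )
    merged = x.merge(y, on="site_id", how="inner")
    merged["cross_state_delta"] = merged["delta_x"] - merged["delta_y"]
    merged["flagged"] = np.abs(merged["cross_state_delta"]) >= log_thr
    merged.insert(1, "state_x", state_x)
    merged.insert(2, "state_y", state_y)
    return merged.sort_values("site_id", kind="mergesort").reset_index(drop=True)


def engagement_by_competition(
    records: Sequence[PeptideQuantRecord],
    layouts: Sequence[PlexLayout],
    database: ProteinDatabase,
    threshold: float = 2.0,
    treatment: str = "inhibitor",
) -> pd.DataFrame:
    """Covalent-inhibitor engagement from probe-labeling competition.

    A site is engaged when treated labeling falls to <= 1/threshold of the
    control; the engagement fraction is 1 - treated/control, clamped to
    [0, 1] (treated > control yields engagement 0 with ``clamped=True``).
    """
    if threshold <= 1:
        raise LigandError(f"threshold must be > 1, got {threshold}")
    deltas = paired_deltas(records, layouts, treatment=treatment)
    if len(deltas) == 0:
        return pd.DataFrame(
            columns=[
                "site_id", "accession", "state", "delta_log2", "ratio",
                "engagement", "engaged", "clamped",
            ]
        )
    mapped = _map_sites(deltas.rename(columns={"delta_log2": "log2_ratio"}), database)
    site_plex = (
        mapped.groupby(["site_id", "accession", "state", "plex"], sort=False)["log2_ratio"]
        .median()
        .reset_index()
    )
    out = (
        site_plex.groupby(["site_id", "accession", "state"], sort=False)["log2_ratio"]
        .median()
        .rename("delta_log2")
        .reset_index()
    )
    out["ratio"] = np.power(2.0, out["delta_log2"])
    out["engagement"] = np.clip(1.0 - out["ratio"], 0.0, 1.0)
    out["engaged"] = out["ratio"] <= 1.0 / threshold
    out["clamped"] = out["ratio"] > 1.0
    return out.sort_values(["site_id", "state"], kind="mergesort").reset_index(drop=True)
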