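"""Evidence-tiered calling of state-dependent cysteine-reactivity changes.

A cysteine site is called only when its probe-labeling signal shifts at least
``fc_threshold``-fold versus the reference state (activated cells) *and* the
shift survives subtraction of an abundance baseline, so that protein
expression changes are not mistaken for reactivity changes. The baseline is
the matched protein's fold change from the unenriched (whole-proteome)
experiment when available, otherwise the leave-one-out median of the
protein's other quantified cysteine sites (which needs at least two other
sites, so single-cysteine proteins can never self-normalize).

Evidence tiers follow the two-peptide rule: a call is ``multi_peptide`` when
the protein has at least ``min_cys_peptides`` distinct quantified
cysteine-containing peptides, ``single_peptide_with_proteome`` when it has
fewer but matching unenriched quantification exists, and otherwise the site
is ``insufficient_evidence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import AnnotationSet


class CallingError(ValueError):
    """Invalid input to reactivity calling."""


@dataclass
class CallParams:
    """Thresholds and modes for reactivity calling.

    ``fc_threshold`` is on the fold-change scale (default 2, i.e. |log2| >= 1
    for both the raw and the abundance-corrected ratio).
    """

    fc_threshold: float = 2.0
    min_cys_peptides: int = 2
    baseline_mode: str = "auto"  # "auto" | "unenriched_protein" | "median_cysteine"
    comparison_conditions: Optional[Sequence[str]] = None
    reference_condition: str = "D2"

    def validate(self) -> "CallParams":
        if not (np.isfinite(self.fc_threshold) and self.fc_threshold > 1):
            raise CallingError(f"fc_threshold must be finite and > 1, got {self.fc_threshold}")
        if self.min_cys_peptides < 1:
            raise CallingError("min_cys_peptides must be >= 1")
        if self.baseline_mode not in {"auto", "unenriched_protein", "median_cysteine"}:
            raise CallingError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.comparison_conditions is not None and self.reference_condition in set(
            self.comparison_conditions
        ):
            raise CallingError("reference condition cannot be a comparison condition")
        return self


CALL_COLUMNS = [
    "site_id",
    "accession",
    "condition",
    "raw_log2fc",
    "baseline_log2fc",
    "baseline_source",
    "corrected_log2fc",
    "direction",
    "verdict",
    "evidence_tier",
    "n_peptides",
    "n_donors_observed",
    "n_donors_pass",
]


def call_reactivity(
    sites: pd.DataFrame,
    proteins: Optional[pd.DataFrame],
    params: CallParams,
) -> pd.DataFrame:
    """Call reactivity changes per site x comparison condition.

    Parameters
    ----------
    sites
        Long site quant from :func:`cysreact.quant.rollup_sites` (columns
        site_id, accession, composite, condition, plex, log2_ratio,
        n_peptides). Donor-level values; the cross-donor median is taken
        here.
    proteins
        Long protein quant from the unenriched experiment (may be ``None``
        or empty when no whole-proteome data exist).
    params
        Thresholds and baseline mode.

    Returns
    -------
    DataFrame with one row per (site, condition) carrying the raw and
    corrected log2 fold changes, direction, verdict and evidence tier.
    """
    params.validate()
    if sites is None or len(sites) == 0:
        raise CallingError("empty site quant input")
    sites = sites[~sites["composite"].astype(bool)].copy()
    if len(sites) == 0:
        raise CallingError("no single-site (non-composite) quantifications")

    threshold = math.log2(params.fc_threshold)
    conditions = params.comparison_conditions
    if conditions is None:
        conditions = [
            c for c in sorted(sites["condition"].unique()) if c != params.reference_condition
        ]

    # cross-donor medians
    raw = (
        sites[sites["condition"].isin(conditions)]
        .groupby(["site_id", "accession", "condition"], sort=False)
        .agg(
            raw_log2fc=("log2_ratio", "median"),
            n_donors_observed=("plex", "nunique"),
            n_donors_pass=("log2_ratio", lambda v: int((np.abs(v) >= threshold).sum())),
        )
        .reset_index()
    )
    n_pep_site = sites.groupby("site_id", sort=False)["n_peptides"].first()
    raw["n_peptides"] = raw["site_id"].map(n_pep_site)
    # protein-level distinct cysteine peptide counts (sum over its sites,
    # composite peptides included in the original n_peptides bookkeeping)
    prot_cys_pep = (
        sites.drop_duplicates("site_id").groupby("accession")["n_peptides"].sum().to_dict()
    )

    prot_fc: dict = {}
    if proteins is not None and len(proteins) > 0:
        pf = (
            proteins[proteins["condition"].isin(conditions)]
            .groupby(["accession", "condition"], sort=False)["log2_ratio"]
            .median()
        )
        prot_fc = pf.to_dict()

    # per (accession, condition): site_id -> raw, for leave-one-out baselines
    site_raw_by_prot: dict = {}
    for row in raw.itertuples():
        site_raw_by_prot.setdefault((row.accession, row.condition), {})[row.site_id] = (
            row.raw_log2fc
        )

    rows = []
    for row in raw.itertuples():
        acc, cond = row.accession, row.condition
        baseline, source = None, "none"
        use_unenriched = params.baseline_mode in {"auto", "unenriched_protein"}
        use_loo = params.baseline_mode in {"auto", "median_cysteine"}
        if use_unenriched and (acc, cond) in prot_fc:
            baseline = float(prot_fc[(acc, cond)])
            source = "unenriched_protein"
        elif use_loo:
            others = [
                v for s, v in site_raw_by_prot[(acc, cond)].items() if s != row.site_id
            ]
            if len(others) >= 2:
                baseline = float(np.median(others))
                source = "median_cysteine"

        n_cys_pep = prot_cys_pep.get(acc, 0)
        has_proteome = (acc, cond) in prot_fc
        if n_cys_pep >= params.min_cys_peptides:
            tier = "multi_peptide"
        elif has_proteome and params.baseline_mode in {"auto", "unenriched_protein"}:
            tier = "single_peptide_with_proteome"
        else:
            tier = "insufficient_evidence"

        raw_fc = float(row.raw_log2fc)
        direction = "higher" if raw_fc > 0 else ("lower" if raw_fc < 0 else "")
        if tier == "insufficient_evidence" or baseline is None:
            verdict = "insufficient_evidence"
            corrected = np.nan if baseline is None else raw_fc - baseline
        else:
            corrected = raw_fc - baseline
            if abs(raw_fc) >= threshold and abs(corrected) >= threshold:
                verdict = "reactivity_change"
            elif abs(raw_fc) >= threshold:
                verdict = "expression_coupled"
            else:
                verdict = "no_change"
        rows.append(
            {
                "site_id": row.site_id,
                "accession": acc,
                "condition": cond,
                "raw_log2fc": raw_fc,
                "baseline_log2fc": np.nan if baseline is None else baseline,
                "baseline_source": source,
                "corrected_log2fc": corrected,
                "direction": direction,
                "verdict": verdict,
                "evidence_tier": tier,
                "n_peptides": int(row.n_peptides),
                "n_donors_observed": int(row.n_donors_observed),
                "n_donors_pass": int(row.n_donors_pass),
            }
        )
    out = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return out.sort_values(["site_id", "condition"], kind="mergesort").reset_index(drop=True)


def summarize_calls(
    calls: pd.DataFrame, annotations: Optional[AnnotationSet] = None
) -> pd.DataFrame:
    """Per-condition counts of higher/lower reactivity changes, by class.

    Without annotations, one row per (condition, direction). With
    annotations, counts are additionally split by class membership of the
    parent protein (a protein in several classes contributes to each).
    """
    hits = calls[calls["verdict"] == "reactivity_change"]
    conditions = sorted(calls["condition"].unique()) if len(calls) else []
    rows = []
    for cond in conditions:
        sub = hits[hits["condition"] == cond]
        if annotations is None:
            rows.append(
                {
                    "condition": cond,
                    "class": "all",
                    "higher": int((sub["direction"] == "higher").sum()),
                    "lower": int((sub["direction"] == "lower").sum()),
                }
            )
        else:
            for name in ["all"] + annotations.class_names:
                if name == "all":
                    members = None
                else:
                    members = annotations.members(name)
                part = sub if members is None else sub[sub["accession"].isin(members)]
                rows.append(
                    {
                        "condition": cond,
                        "class": name,
                        "higher": int((part["direction"] == "higher").sum()),
                        "lower": int((part["direction"] == "lower").sum()),
                    }
                )
    out = pd.DataFrame(rows, columns=["condition", "class", "higher", "lower"])
    out["total"] = out["higher"] + out["lower"]
    return out
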