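"""Channel normalization, condition-vs-reference ratios, and site/protein rollup.

Conventions
-----------
* Normalization factors are estimated within each plex from complete-case
  records (observed in every channel of that plex), so missingness cannot
  bias the estimate. Two estimators are provided: ``"total"`` equalizes
  per-channel total intensity ("normalization by protein content") and
  ``"median"`` (default in the pipeline) removes the per-channel median of
  record-centered log2 intensities, which is robust to a minority of truly
  changing peptides.
* The reference value of a record is the geometric mean of its observed
  reference-condition channels (arithmetic mean in log2 space); a condition's
  ratio is the median over that condition's channel ratios.
* Donor (plex) level values are kept separate through rollup; cross-donor
  aggregation happens at calling time.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import PeptideQuantRecord, PlexLayout, ProteinDatabase

logger = logging.getLogger(__name__)


class QuantError(ValueError):
    """Invalid input to a quantification operation."""


class PeptideMappingError(QuantError):
    """A peptide's base sequence does not occur in its protein's sequence."""


# ---------------------------------------------------------------------------
# Long-format conversion
# ---------------------------------------------------------------------------

def records_to_long(
    records: Iterable[PeptideQuantRecord], layouts: Sequence[PlexLayout]
) -> pd.DataFrame:
    """Flatten records into a long frame with layout metadata per channel."""
    meta = {}
    for layout in layouts:
        for ch in layout.channels:
            meta[(layout.plex_id, ch.label)] = (ch.condition, ch.replicate, ch.treatment)
    rows = []
    for rec in records:
        offsets = ";".join(str(o) for o in rec.modified_offsets)
        for label, value in rec.intensities.items():
            condition, replicate, treatment = meta[(rec.plex_id, label)]
            rows.append(
                (
                    rec.plex_id,
                    rec.protein_accession,
                    rec.base_sequence,
                    offsets,
                    label,
                    condition,
                    replicate,
                    treatment,
                    value,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "plex",
            "accession",
            "sequence",
            "offsets",
            "channel",
            "condition",
            "replicate",
            "treatment",
            "intensity",
        ],
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_channels(
    records: Sequence[PeptideQuantRecord],
    layouts: Sequence[PlexLayout],
    method: str = "median",
) -> Tuple[List[PeptideQuantRecord], pd.DataFrame]:
    """Rescale channels within each plex; returns (records, factor table).

    ``method="total"`` makes each channel's total intensity (over
    complete-case records) equal to the across-channel mean total.
    ``method="median"`` centers the per-channel median of record-centered
    log2 intensities (factors are mean-centered in log space, so the overall
    intensity scale is preserved and the operation is idempotent).
    """
    if method not in {"total", "median"}:
        raise QuantError(f"unknown normalization method {method!r}")
    by_plex = {layout.plex_id: layout for layout in layouts}
    factor_rows = []
    factors: Dict[Tuple[str, str], float] = {}
    grouped: Dict[str, List[PeptideQuantRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.plex_id, []).append(rec)
    for plex_id, layout in by_plex.items():
        recs = grouped.get(plex_id, [])
        if not recs:
            raise QuantError(f"plex {plex_id!r}: no records to normalize")
        labels = layout.channel_labels
        complete = [r for r in recs if all(l in r.intensities for l in labels)]
        if not complete:
            raise QuantError(f"plex {plex_id!r}: no complete-case records")
        matrix = np.array([[r.intensities[l] for l in labels] for r in complete])
        if method == "total":
            totals = matrix.sum(axis=0)
            if np.any(totals == 0):
                zero = [labels[i] for i in np.flatnonzero(totals == 0)]
                raise QuantError(f"plex {plex_id!r}: zero total intensity in channels {zero}")
            f = totals.mean() / totals
        else:
            if np.any(matrix == 0):
                raise QuantError(
                    f"plex {plex_id!r}: zero intensity in a complete-case record; "
                    "median normalization needs positive values"
                )
            log2m = np.log2(matrix)
            centered = log2m - log2m.mean(axis=1, keepdims=True)
            med = np.median(centered, axis=0)
            med = med - med.mean()  # preserve overall scale; makes op idempotent
            f = np.power(2.0, -med)
        for label, factor in zip(labels, f):
            factors[(plex_id, label)] = float(factor)
            factor_rows.append({"plex": plex_id, "channel": label, "factor": float(factor)})
        logger.info("plex %s: normalization factors %s", plex_id, dict(zip(labels, f)))
    out = [
        PeptideQuantRecord(
            protein_accession=rec.protein_accession,
            base_sequence=rec.base_sequence,
            modified_offsets=rec.modified_offsets,
            intensities={
                label: value * factors[(rec.plex_id, label)]
                for label, value in rec.intensities.items()
            },
            plex_id=rec.plex_id,
        )
        for rec in records
    ]
    return out, pd.DataFrame(factor_rows, columns=["plex", "channel", "factor"])


# ---------------------------------------------------------------------------
# Condition ratios
# ---------------------------------------------------------------------------

def condition_ratios(
    records: Sequence[PeptideQuantRecord], layouts: Sequence[PlexLayout]
) -> pd.DataFrame:
    """Per-record, per-condition log2 ratio versus the plex reference.

    The reference value is the geometric mean of the record's observed
    reference-condition channels; records with no observed reference channel
    are dropped (the count is logged). Returns a long frame with columns
    plex, accession, sequence, offsets, condition, log2_ratio.
    """
    long = records_to_long(records, layouts)
    if len(long) == 0:
        return pd.DataFrame(
            columns=["plex", "accession", "sequence", "offsets", "condition", "log2_ratio"]
        )
    ref_by_plex = {layout.plex_id: layout.reference_condition for layout in layouts}
    long = long[long["intensity"] > 0].copy()
    long["log2i"] = np.log2(long["intensity"])
    long["is_ref"] = long["condition"] == long["plex"].map(ref_by_plex)
    key = ["plex", "accession", "sequence", "offsets"]
    ref = (
        long[long["is_ref"]]
        .groupby(key, sort=False)["log2i"]
        .mean()
        .rename("ref_log2")
        .reset_index()
    )
    merged = long.merge(ref, on=key, how="left")
    dropped = merged["ref_log2"].isna()
    if dropped.any():
        n_dropped = merged.loc[dropped, key].drop_duplicates().shape[0]
        logger.info("condition_ratios: dropped %d records with no reference channel", n_dropped)
    merged = merged[~dropped].copy()
    merged["ratio"] = merged["log2i"] - merged["ref_log2"]
    out = (
        merged.groupby(key + ["condition"], sort=False)["ratio"]
        .median()
        .rename("log2_ratio")
        .reset_index()
    )
    return out.sort_values(key + ["condition"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Rollup
# ---------------------------------------------------------------------------

def _map_sites(ratios: pd.DataFrame, database: ProteinDatabase) -> pd.DataFrame:
    """Attach site_id / composite columns by locating peptides in the database."""
    peptides = ratios[["accession", "sequence", "offsets"]].drop_duplicates()
    site_ids, composites = {}, {}
    for row in peptides.itertuples(index=False):
        acc, seq, offsets = row.accession, row.sequence, row.offsets
        if acc not in database:
            raise PeptideMappingError(f"accession {acc!r} not in database")
        start = database[acc].find(seq)
        if start < 0:
            raise PeptideMappingError(
                f"peptide {seq!r} not found in protein {acc!r}"
            )
        offs = [int(x) for x in str(offsets).split(";") if x != ""]
        if not offs:
            raise QuantError(f"peptide {seq!r} of {acc!r} has no modified offset")
        residues = [start + o for o in offs]  # 1-based protein residues
        site_ids[(acc, seq, offsets)] = (
            f"{acc}_" + "_".join(f"C{r}" for r in residues)
        )
        composites[(acc, seq, offsets)] = len(residues) > 1
    out = ratios.copy()
    keys = list(zip(out["accession"], out["sequence"], out["offsets"]))
    out["site_id"] = [site_ids[k] for k in keys]
    out["composite"] = [composites[k] for k in keys]
    return out


def rollup_sites(ratios: pd.DataFrame, database: ProteinDatabase) -> pd.DataFrame:
    """Aggregate enriched peptide ratios to cysteine sites.

    The residue number is the peptide's first exact occurrence in the protein
    plus the in-peptide offset (1-based). The site value per (condition,
    donor) is the median of contributing peptide ratios; ``n_peptides``
    counts distinct base sequences supporting the site. Peptides carrying
    more than one modified cysteine map to a composite site id (joined
    residue numbers) flagged ``composite=True`` so callers can exclude them
    from single-site calling.
    """
    if len(ratios) == 0:
        return pd.DataFrame(
            columns=[
                "site_id", "accession", "composite", "condition", "plex",
                "log2_ratio", "n_peptides",
            ]
        )
    mapped = _map_sites(ratios, database)
    values = (
        mapped.groupby(["site_id", "accession", "composite", "condition", "plex"], sort=False)[
            "log2_ratio"
        ]
        .median()
        .reset_index()
    )
    n_pep = (
        mapped.groupby("site_id", sort=False)["sequence"]
        .nunique()
        .rename("n_peptides")
        .reset_index()
    )
    out = values.merge(n_pep, on="site_id", how="left")
    return out.sort_values(
        ["site_id", "condition", "plex"], kind="mergesort"
    ).reset_index(drop=True)


def rollup_proteins(ratios: pd.DataFrame) -> pd.DataFrame:
    """Aggregate unenriched peptide ratios to proteins (median per condition, donor)."""
    if len(ratios) == 0:
        return pd.DataFrame(
            columns=["accession", "condition", "plex", "log2_ratio", "n_peptides"]
        )
    values = (
        ratios.groupby(["accession", "condition", "plex"], sort=False)["log2_ratio"]
        .median()
        .reset_index()
    )
    n_pep = (
        ratios.groupby("accession", sort=False)["sequence"]
        .nunique()
        .rename("n_peptides")
        .reset_index()
    )
    out = values.merge(n_pep, on="accession", how="left")
    return out.sort_values(
        ["accession", "condition", "plex"], kind="mergesort"
    ).reset_index(drop=True)


def intersect_sites(
    set_a: pd.DataFrame, set_b: pd.DataFrame
) -> Tuple[List[str], Dict[str, int]]:
    """Sites quantified in both inputs, with A-only/B-only/both counts."""
    ids_a = set(set_a["site_id"].unique())
    ids_b = set(set_b["site_id"].unique())
    both = sorted(ids_a & ids_b)
    counts = {
        "both": len(both),
        "a_only": len(ids_a - ids_b),
        "b_only": len(ids_b - ids_a),
    }
    return both, counts
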