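"""Synthetic multiplexed chemoproteomics and metabolomics data with planted truth.

The generator emulates the study design the pipeline targets: primary human T
cells in five states (activated D2; acutely stimulated D4A/D8A; chronically
stimulated D4C/D8C) profiled by 10-plex TMT experiments, one plex per donor,
in two parallel arms — probe-enriched cysteine peptides (reactivity) and an
unenriched whole-proteome run (abundance baseline) — plus a 16-plex ATP
add-back experiment (D2/D8A/D8C x control/+ATP) and cell-volume-annotated
metabolite/lipid feature tables with isotope-tracing isotopologues.

Intensity model (log2 space)::

    log2 I = base(peptide) + donor(protein, plex)
             + abundance_offset(protein, condition)
             + reactivity_offset(site, condition)     # enriched only
             + occlusion(site, state)                  # ATP arm only
             + Normal(0, noise_sd_log2)

Missingness is applied after noise, by default intensity-dependent (logistic
in log2 intensity, calibrated so the overall missing fraction matches
``missing_rate``), with an MCAR fallback. Every planted effect is recorded in
a :class:`GroundTruth` object sufficient to score any downstream call set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    AnnotationSet,
    ChannelAssignment,
    DataModelError,
    PeptideQuantRecord,
    PlexLayout,
    ProteinDatabase,
)

TMT10 = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131"]
TMT16 = [
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
]

# residues used for random segments: no C (placed explicitly), no K/R
# (reserved for tryptic termini)
_SEGMENT_AA = "ADEFGHILMNPQSTVWY"


class SimulationError(ValueError):
    """Infeasible or invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults mirror the profiled study conditions: five T cell states times
    two channels in a TMT 10-plex, one plex per donor, five donors,
    multiplicative (log-normal) reporter noise of 0.25 log2 units, 20%
    intensity-dependent missingness, and 5% planted 4-fold effects.
    """

    seed: int
    n_proteins: int = 500
    cys_sites_per_protein: Tuple[int, int] = (1, 3)
    peptides_per_site: Tuple[int, int] = (1, 3)
    noncys_peptides_per_protein: Tuple[int, int] = (3, 6)
    conditions: Tuple[str, ...] = ("D2", "D4A", "D4C", "D8A", "D8C")
    reference_condition: str = "D2"
    channels_per_condition: int = 2
    n_donors: int = 5
    base_log2_mean: float = 16.0
    base_log2_sd: float = 1.5
    donor_sd_log2: float = 0.1
    noise_sd_log2: float = 0.25
    missing_rate: float = 0.2
    missing_mode: str = "logistic"  # "logistic" (intensity-dependent) or "mcar"
    missing_steepness: float = 0.8
    planted_expression: Tuple[float, float] = (0.05, 2.0)
    planted_reactivity: Tuple[float, float] = (0.05, 2.0)
    planted_atp: Tuple[float, float] = (0.05, 2.0)
    atp_state_specific: bool = True
    atp_states: Tuple[str, ...] = ("D2", "D8A", "D8C")
    addback_n_donors: int = 2
    addback_replicates: Tuple[Tuple[str, int], ...] = (("D2", 3), ("D8A", 3), ("D8C", 2))
    nucleotide_class_prob: float = 0.15
    mito_class_prob: float = 0.20
    atp_class_odds: float = 8.0
    # metabolomics / tracing
    n_metab_features: int = 150
    metab_conditions: Tuple[str, ...] = ("D2", "D8A", "D8C")
    metab_n_donors: int = 4
    metab_noise_sd_log2: float = 0.2
    metab_missing_rate: float = 0.05
    planted_metab: Tuple[float, float] = (0.1, 1.0)
    cell_volumes_fl: Tuple[Tuple[str, float], ...] = (("D2", 480.0), ("D8A", 400.0), ("D8C", 330.0))
    mean_cell_count: float = 2.0e6
    p_nat_13c: float = 0.0107
    tracer_noise_sd: float = 0.01

    def validate(self) -> "SimulationConfig":
        for name in ("planted_expression", "planted_reactivity", "planted_atp", "planted_metab"):
            frac, eff = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"{name}: fraction {frac} outside [0, 1]")
            if not np.isfinite(eff):
                raise SimulationError(f"{name}: effect {eff} not finite")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise SimulationError(f"missing_rate {self.missing_rate} outside [0, 1]")
        if self.missing_mode not in {"logistic", "mcar"}:
            raise SimulationError(f"unknown missing_mode {self.missing_mode!r}")
        if self.reference_condition not in self.conditions:
            raise SimulationError("reference_condition must be among conditions")
        if self.n_proteins < 1 or self.n_donors < 1:
            raise SimulationError("n_proteins and n_donors must be >= 1")
        return self


@dataclass
class SimulatedProteome:
    """Sequences plus the peptide geometry the experiment simulators draw from."""

    database: ProteinDatabase
    annotations: AnnotationSet
    #: one row per cysteine site: accession, site_id, residue
    sites: pd.DataFrame
    #: one row per enriched peptide form: accession, site_id, sequence, offset
    enriched_peptides: pd.DataFrame
    #: one row per unenriched peptide: accession, sequence
    unenriched_peptides: pd.DataFrame


@dataclass
class GroundTruth:
    """Planted effects, sufficient to score any downstream call set."""

    #: accession, condition, log2_offset
    protein_effects: pd.DataFrame
    #: site_id, accession, condition, log2_offset
    site_effects: pd.DataFrame
    #: site_id, accession, state, occlusion_log2
    atp_effects: pd.DataFrame
    #: class_name, accession (class memberships used for planting)
    classes: pd.DataFrame
    #: feature, condition, log2_offset (metabolomics; may be empty)
    metabolite_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["feature", "condition", "log2_offset"])
    )

    def to_table(self) -> pd.DataFrame:
        """Serialize all planted effects to one long table."""
        parts = []
        for effect_type, frame, id_col, ctx_col, val_col in [
            ("expression", self.protein_effects, "accession", "condition", "log2_offset"),
            ("reactivity", self.site_effects, "site_id", "condition", "log2_offset"),
            ("atp", self.atp_effects, "site_id", "state", "occlusion_log2"),
            ("metabolite", self.metabolite_effects, "feature", "condition", "log2_offset"),
        ]:
            if len(frame) == 0:
                continue
            part = pd.DataFrame(
                {
                    "effect_type": effect_type,
                    "id": frame[id_col].astype(str),
                    "accession": frame["accession"].astype(str)
                    if "accession" in frame.columns
                    else "",
                    "context": frame[ctx_col].astype(str),
                    "value": frame[val_col].astype(float),
                }
            )
            parts.append(part)
        if len(self.classes) > 0:
            parts.append(
                pd.DataFrame(
                    {
                        "effect_type": "class",
                        "id": self.classes["accession"].astype(str),
                        "accession": self.classes["accession"].astype(str),
                        "context": self.classes["class_name"].astype(str),
                        "value": np.nan,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=["effect_type", "id", "accession", "context", "value"])
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(["effect_type", "id", "context"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GroundTruth":
        def take(effect_type, id_col, ctx_col, val_col):
            sub = table[table["effect_type"] == effect_type]
            frame = pd.DataFrame(
                {
                    id_col: sub["id"].astype(str),
                    "accession": sub["accession"].astype(str),
                    ctx_col: sub["context"].astype(str),
                    val_col: sub["value"].astype(float),
                }
            )
            return frame.reset_index(drop=True)

        classes_sub = table[table["effect_type"] == "class"]
        classes = pd.DataFrame(
            {
                "class_name": classes_sub["context"].astype(str),
                "accession": classes_sub["accession"].astype(str),
            }
        ).reset_index(drop=True)
        return cls(
            protein_effects=take("expression", "accession", "condition", "log2_offset")[
                ["accession", "condition", "log2_offset"]
            ],
            site_effects=take("reactivity", "site_id", "condition", "log2_offset"),
            atp_effects=take("atp", "site_id", "state", "occlusion_log2"),
            classes=classes,
            metabolite_effects=take("metabolite", "feature", "condition", "log2_offset")[
                ["feature", "condition", "log2_offset"]
            ],
        )


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def _random_segment(rng: np.random.Generator, length: int, cys_pos: int | None) -> str:
    """A tryptic segment: random residues, optional C, terminal K/R."""
    body = rng.choice(list(_SEGMENT_AA), size=length - 1)
    if cys_pos is not None:
        body[cys_pos] = "C"
    terminal = "K" if rng.random() < 0.5 else "R"
    return "".join(body) + terminal


def simulate_proteome(config: SimulationConfig) -> Tuple[SimulatedProteome, GroundTruth]:
    """Generate random proteins with tryptic cysteine peptides and plant effects.

    Each cysteine site sits inside a 6-25-residue tryptic segment; additional
    peptide forms for a site are missed-cleavage extensions into the flanking
    cysteine-free segments, so every enriched peptide form carries exactly one
    modified cysteine. Annotation classes ("nucleotide_binding",
    "mitochondrial") are drawn per protein; ATP-occluded sites are sampled
    with odds ``atp_class_odds`` in favor of nucleotide-binding proteins
    (odds 1 = independence).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    site_rows: List[dict] = []
    enriched_rows: List[dict] = []
    unenriched_rows: List[dict] = []
    sequences: Dict[str, str] = {}

    lo_s, hi_s = config.cys_sites_per_protein
    lo_p, hi_p = config.peptides_per_site
    lo_u, hi_u = config.noncys_peptides_per_protein
    if lo_s < 1:
        raise SimulationError("cys_sites_per_protein lower bound must be >= 1")

    width = len(str(config.n_proteins))
    for ip in range(config.n_proteins):
        accession = f"SIM{ip + 1:0{width}d}"
        for _attempt in range(20):
            n_sites = int(rng.integers(lo_s, hi_s + 1))
            n_noncys = max(int(rng.integers(lo_u, hi_u + 1)), n_sites + 1)
            # segments: alternate noncys / site so that missed-cleavage
            # extensions of a site peptide never pick up a second cysteine
            noncys_segments = []
            for _ in range(n_noncys):
                length = int(rng.integers(6, 21))
                noncys_segments.append(_random_segment(rng, length, None))
            site_segments = []
            cys_positions = []
            for _ in range(n_sites):
                length = int(rng.integers(6, 21))
                pos = int(rng.integers(0, length - 1))
                site_segments.append(_random_segment(rng, length, pos))
                cys_positions.append(pos)
            order: List[Tuple[str, int]] = []  # (kind, index)
            for i in range(n_sites):
                order.append(("noncys", i))
                order.append(("site", i))
            for i in range(n_sites, n_noncys):
                order.append(("noncys", i))
            segments = [
                noncys_segments[i] if kind == "noncys" else site_segments[i]
                for kind, i in order
            ]
            sequence = "".join(segments)
            starts = np.cumsum([0] + [len(s) for s in segments[:-1]])

            ok = True
            prot_site_rows, prot_enriched_rows, prot_unenriched_rows = [], [], []
            for pos_in_order, (kind, i) in enumerate(order):
                if kind != "site":
                    continue
                seg = segments[pos_in_order]
                seg_start = int(starts[pos_in_order])
                residue = seg_start + cys_positions[i] + 1  # 1-based in protein
                site_id = f"{accession}_C{residue}"
                n_forms = int(rng.integers(lo_p, hi_p + 1))
                forms: List[Tuple[str, int]] = [(seg, cys_positions[i] + 1)]
                prev_seg = segments[pos_in_order - 1]
                if n_forms >= 2:
                    forms.append((prev_seg + seg, len(prev_seg) + cys_positions[i] + 1))
                if n_forms >= 3 and pos_in_order + 1 < len(segments):
                    nxt = segments[pos_in_order + 1]
                    if "C" not in nxt:
                        forms.append((seg + nxt, cys_positions[i] + 1))
                for seq_form, offset in forms:
                    # first-occurrence mapping must resolve to the intended site
                    start = sequence.find(seq_form)
                    if start + offset != residue:
                        ok = False
                        break
                    prot_enriched_rows.append(
                        {
                            "accession": accession,
                            "site_id": site_id,
                            "sequence": seq_form,
                            "offset": offset,
                        }
                    )
                if not ok:
                    break
                prot_site_rows.append(
                    {"accession": accession, "site_id": site_id, "residue": residue}
                )
            if ok:
                for pos_in_order, (kind, i) in enumerate(order):
                    if kind != "noncys":
                        continue
                    seq_form = segments[pos_in_order]
                    if sequence.find(seq_form) != int(starts[pos_in_order]):
                        ok = False
                        break
                    prot_unenriched_rows.append(
                        {"accession": accession, "sequence": seq_form}
                    )
            if ok:
                sequences[accession] = sequence
                site_rows.extend(prot_site_rows)
                enriched_rows.extend(prot_enriched_rows)
                unenriched_rows.extend(prot_unenriched_rows)
                break
        else:
            raise SimulationError(f"could not place peptides for protein {accession}")

    database = ProteinDatabase(sequences)
    accessions = sorted(sequences)
    acc_arr = np.array(accessions)

    nb_mask = rng.random(len(accessions)) < config.nucleotide_class_prob
    mito_mask = rng.random(len(accessions)) < config.mito_class_prob
    annotations = AnnotationSet(
        {
            "nucleotide_binding": acc_arr[nb_mask].tolist(),
            "mitochondrial": acc_arr[mito_mask].tolist(),
        }
    )
    classes = pd.DataFrame(
        [{"class_name": name, "accession": acc} for name, members in annotations.items()
         for acc in sorted(members)]
    )
    if len(classes) == 0:
        classes = pd.DataFrame(columns=["class_name", "accession"])

    sites = pd.DataFrame(site_rows)
    enriched = pd.DataFrame(enriched_rows)
    unenriched = pd.DataFrame(unenriched_rows)

    non_ref = [c for c in config.conditions if c != config.reference_condition]

    # --- planted expression shifts (fraction of proteins) ------------------
    frac_e, eff_e = config.planted_expression
    n_expr = int(round(frac_e * len(accessions)))
    expr_acc = rng.choice(acc_arr, size=n_expr, replace=False) if n_expr else np.array([], dtype=acc_arr.dtype)
    protein_effects = pd.DataFrame(
        {
            "accession": expr_acc,
            "condition": rng.choice(non_ref, size=n_expr) if n_expr else np.array([], dtype=object),
            "log2_offset": (rng.choice([-1.0, 1.0], size=n_expr) * eff_e) if n_expr else np.array([]),
        }
    )

    # --- planted reactivity shifts (fraction of sites, disjoint proteins) --
    frac_r, eff_r = config.planted_reactivity
    expr_set = set(expr_acc.tolist())
    eligible = sites[~sites["accession"].isin(expr_set)]
    n_react = int(round(frac_r * len(sites)))
    n_react = min(n_react, len(eligible))
    react_idx = (
        rng.choice(eligible.index.to_numpy(), size=n_react, replace=False)
        if n_react
        else np.array([], dtype=int)
    )
    react_sites = sites.loc[react_idx]
    site_effects = pd.DataFrame(
        {
            "site_id": react_sites["site_id"].to_numpy(),
            "accession": react_sites["accession"].to_numpy(),
            "condition": rng.choice(non_ref, size=n_react) if n_react else np.array([], dtype=object),
            "log2_offset": (rng.choice([-1.0, 1.0], size=n_react) * eff_r) if n_react else np.array([]),
        }
    )

    # --- planted ATP-occluded sites (class-weighted sampling) --------------
    frac_a, eff_a = config.planted_atp
    n_atp = int(round(frac_a * len(sites)))
    nb_set = set(acc_arr[nb_mask].tolist())
    weights = np.where(sites["accession"].isin(nb_set), config.atp_class_odds, 1.0)
    weights = weights / weights.sum()
    atp_idx = (
        rng.choice(sites.index.to_numpy(), size=n_atp, replace=False, p=weights)
        if n_atp
        else np.array([], dtype=int)
    )
    atp_sites = sites.loc[atp_idx]
    occl_states = ["D8C"] if config.atp_state_specific else list(config.atp_states)
    atp_effects = pd.DataFrame(
        [
            {
                "site_id": row.site_id,
                "accession": row.accession,
                "state": state,
                "occlusion_log2": -abs(eff_a),
            }
            for row in atp_sites.itertuples()
            for state in occl_states
        ],
        columns=["site_id", "accession", "state", "occlusion_log2"],
    )

    truth = GroundTruth(
        protein_effects=protein_effects.reset_index(drop=True),
        site_effects=site_effects.reset_index(drop=True),
        atp_effects=atp_effects.reset_index(drop=True),
        classes=classes,
    )
    proteome = SimulatedProteome(
        database=database,
        annotations=annotations,
        sites=sites.reset_index(drop=True),
        enriched_peptides=enriched.reset_index(drop=True),
        unenriched_peptides=unenriched.reset_index(drop=True),
    )
    return proteome, truth


# ---------------------------------------------------------------------------
# TMT experiments
# ---------------------------------------------------------------------------

def _offset_lookup(frame: pd.DataFrame, key_cols: Sequence[str], value_col: str) -> Dict[tuple, float]:
    return {
        tuple(row[c] for c in key_cols): float(row[value_col])
        for _, row in frame.iterrows()
    }


def _apply_missingness(
    log2_matrix: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of missing cells, applied after noise."""
    if config.missing_rate <= 0:
        return np.zeros(log2_matrix.shape, dtype=bool)
    if config.missing_mode == "mcar":
        return rng.random(log2_matrix.shape) < config.missing_rate
    # intensity-dependent: logistic decreasing in log2 intensity, centered at
    # the missing_rate quantile so the realized overall rate ~ missing_rate
    x0 = np.quantile(log2_matrix, config.missing_rate)
    p_miss = 1.0 / (1.0 + np.exp(config.missing_steepness * (log2_matrix - x0)))
    return rng.random(log2_matrix.shape) < p_miss


def _records_from_matrix(
    peptides: pd.DataFrame,
    log2_matrix: np.ndarray,
    missing: np.ndarray,
    labels: Sequence[str],
    plex_id: str,
    enriched: bool,
) -> List[PeptideQuantRecord]:
    intens = np.power(2.0, log2_matrix)
    records: List[PeptideQuantRecord] = []
    for r, row in enumerate(peptides.itertuples()):
        values = {
            labels[c]: float(intens[r, c])
            for c in range(len(labels))
            if not missing[r, c]
        }
        if not values:
            continue
        records.append(
            PeptideQuantRecord(
                protein_accession=row.accession,
                base_sequence=row.sequence,
                modified_offsets=(int(row.offset),) if enriched else (),
                intensities=values,
                plex_id=plex_id,
            )
        )
    return records


def _make_layouts(
    conditions: Sequence[str],
    channels_per_condition: int,
    n_donors: int,
    reference: str,
) -> List[PlexLayout]:
    n_channels = len(conditions) * channels_per_condition
    if n_channels == 10:
        labels = TMT10
    elif n_channels == 16:
        labels = TMT16
    else:
        labels = [f"ch{i + 1:02d}" for i in range(n_channels)]
    layouts = []
    for d in range(n_donors):
        channels = []
        k = 0
        for cond in conditions:
            for rep in range(1, channels_per_condition + 1):
                channels.append(
                    ChannelAssignment(label=labels[k], condition=cond, replicate=rep)
                )
                k += 1
        layouts.append(
            PlexLayout(plex_id=f"plex{d + 1}", channels=channels, reference_condition=reference)
        )
    return layouts


def simulate_experiment(
    config: SimulationConfig, proteome: SimulatedProteome, truth: GroundTruth
) -> Tuple[List[PeptideQuantRecord], List[PeptideQuantRecord], List[PlexLayout]]:
    """Realize enriched and unenriched TMT intensities, one plex per donor."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    layouts = _make_layouts(
        config.conditions, config.channels_per_condition, config.n_donors,
        config.reference_condition,
    )
    labels = layouts[0].channel_labels
    cond_of_channel = [c.condition for c in layouts[0].channels]

    prot_off = _offset_lookup(truth.protein_effects, ["accession", "condition"], "log2_offset")
    site_off = _offset_lookup(truth.site_effects, ["site_id", "condition"], "log2_offset")

    enriched_pep = proteome.enriched_peptides
    unenriched_pep = proteome.unenriched_peptides
    accessions = sorted(proteome.database)
    acc_index = {a: i for i, a in enumerate(accessions)}

    base_e = rng.normal(config.base_log2_mean, config.base_log2_sd, len(enriched_pep))
    base_u = rng.normal(config.base_log2_mean, config.base_log2_sd, len(unenriched_pep))

    prot_cond_e = np.array(
        [
            [prot_off.get((row.accession, cond), 0.0) for cond in cond_of_channel]
            for row in enriched_pep.itertuples()
        ]
    )
    site_cond_e = np.array(
        [
            [site_off.get((row.site_id, cond), 0.0) for cond in cond_of_channel]
            for row in enriched_pep.itertuples()
        ]
    )
    prot_cond_u = np.array(
        [
            [prot_off.get((row.accession, cond), 0.0) for cond in cond_of_channel]
            for row in unenriched_pep.itertuples()
        ]
    )

    acc_e = enriched_pep["accession"].map(acc_index).to_numpy()
    acc_u = unenriched_pep["accession"].map(acc_index).to_numpy()

    enriched_records: List[PeptideQuantRecord] = []
    unenriched_records: List[PeptideQuantRecord] = []
    for layout in layouts:
        donor_eff = (
            rng.normal(0.0, config.donor_sd_log2, len(accessions))
            if config.donor_sd_log2 > 0
            else np.zeros(len(accessions))
        )
        for peptides, base, prot_cond, site_cond, acc_ix, enriched_flag, sink in [
            (enriched_pep, base_e, prot_cond_e, site_cond_e, acc_e, True, enriched_records),
            (unenriched_pep, base_u, prot_cond_u, None, acc_u, False, unenriched_records),
        ]:
            if len(peptides) == 0:
                continue
            log2m = base[:, None] + donor_eff[acc_ix][:, None] + prot_cond
            if site_cond is not None:
                log2m = log2m + site_cond
            if config.noise_sd_log2 > 0:
                log2m = log2m + rng.normal(0.0, config.noise_sd_log2, log2m.shape)
            missing = _apply_missingness(log2m, config, rng)
            sink.extend(
                _records_from_matrix(
                    peptides, log2m, missing, labels, layout.plex_id, enriched_flag
                )
            )
    return enriched_records, unenriched_records, layouts


def simulate_atp_addback(
    config: SimulationConfig, proteome: SimulatedProteome, truth: GroundTruth
) -> Tuple[List[PeptideQuantRecord], List[PlexLayout]]:
    """Realize the 16-plex ATP add-back experiment (states x control/+ATP)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 2])

    channels: List[ChannelAssignment] = []
    labels = TMT16
    k = 0
    for state, n_rep in config.addback_replicates:
        for treatment in ("none", "ATP"):
            for rep in range(1, n_rep + 1):
                channels.append(
                    ChannelAssignment(
                        label=labels[k], condition=state, replicate=rep, treatment=treatment
                    )
                )
                k += 1
    if k != 16:
        labels = [f"ch{i + 1:02d}" for i in range(k)]
        channels = [replace(c, label=labels[i]) for i, c in enumerate(channels)]

    layouts = [
        PlexLayout(
            plex_id=f"abplex{d + 1}",
            channels=list(channels),
            reference_condition=config.addback_replicates[0][0],
        )
        for d in range(config.addback_n_donors)
    ]
    chan_meta = layouts[0].channels
    cond_of_channel = [c.condition for c in chan_meta]
    atp_arm = np.array([c.treatment == "ATP" for c in chan_meta])

    prot_off = _offset_lookup(truth.protein_effects, ["accession", "condition"], "log2_offset")
    site_off = _offset_lookup(truth.site_effects, ["site_id", "condition"], "log2_offset")
    occl = _offset_lookup(truth.atp_effects, ["site_id", "state"], "occlusion_log2")

    peptides = proteome.enriched_peptides
    accessions = sorted(proteome.database)
    acc_index = {a: i for i, a in enumerate(accessions)}
    acc_ix = peptides["accession"].map(acc_index).to_numpy()
    base = rng.normal(config.base_log2_mean, config.base_log2_sd, len(peptides))

    fixed = np.zeros((len(peptides), len(chan_meta)))
    for r, row in enumerate(peptides.itertuples()):
        for c, cond in enumerate(cond_of_channel):
            value = prot_off.get((row.accession, cond), 0.0) + site_off.get(
                (row.site_id, cond), 0.0
            )
            if atp_arm[c]:
                value += occl.get((row.site_id, cond), 0.0)
            fixed[r, c] = value

    records: List[PeptideQuantRecord] = []
    for layout in layouts:
        donor_eff = (
            rng.normal(0.0, config.donor_sd_log2, len(accessions))
            if config.donor_sd_log2 > 0
            else np.zeros(len(accessions))
        )
        log2m = base[:, None] + donor_eff[acc_ix][:, None] + fixed
        if config.noise_sd_log2 > 0:
            log2m = log2m + rng.normal(0.0, config.noise_sd_log2, log2m.shape)
        missing = _apply_missingness(log2m, config, rng)
        records.extend(
            _records_from_matrix(
                peptides, log2m, missing, layout.channel_labels, layout.plex_id, True
            )
        )
    return records, layouts


# ---------------------------------------------------------------------------
# Metabolomics and isotope tracing
# ---------------------------------------------------------------------------

def simulate_feature_table(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Metabolite feature intensities plus per-sample cell counts and volumes.

    Returns ``(intensities, sample_metadata, planted_effects)``. Intensities
    scale with total sampled biovolume (cell_count x mean_cell_volume), so
    cell-volume normalization is required before conditions are comparable —
    the profiled states differ in cell size.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    features = [f"met{i + 1:04d}" for i in range(config.n_metab_features)]
    conditions = list(config.metab_conditions)
    reference = conditions[0]
    volumes = dict(config.cell_volumes_fl)

    frac, eff = config.planted_metab
    n_planted = int(round(frac * len(features)))
    planted_ix = rng.choice(len(features), size=n_planted, replace=False) if n_planted else []
    non_ref = [c for c in conditions if c != reference]
    planted_rows = []
    offsets: Dict[Tuple[str, str], float] = {}
    for ix in planted_ix:
        cond = str(rng.choice(non_ref))
        sign = float(rng.choice([-1.0, 1.0]))
        offsets[(features[ix], cond)] = sign * eff
        planted_rows.append(
            {"feature": features[ix], "condition": cond, "log2_offset": sign * eff}
        )
    planted = pd.DataFrame(planted_rows, columns=["feature", "condition", "log2_offset"])

    base = rng.normal(18.0, 1.5, len(features))  # log2 per-volume abundance
    samples, meta_rows = [], []
    data: Dict[str, np.ndarray] = {}
    for cond in conditions:
        for donor in range(1, config.metab_n_donors + 1):
            sample = f"{cond}_d{donor}"
            samples.append(sample)
            count = config.mean_cell_count * float(np.exp(rng.normal(0.0, 0.05)))
            volume = volumes.get(cond, 400.0)
            meta_rows.append(
                {
                    "sample": sample,
                    "condition": cond,
                    "donor": donor,
                    "cell_count": count,
                    "mean_cell_volume": volume,
                }
            )
            shift = np.array([offsets.get((f, cond), 0.0) for f in features])
            log2v = base + shift + rng.normal(0.0, config.metab_noise_sd_log2, len(features))
            values = np.power(2.0, log2v) * count * volume
            if config.metab_missing_rate > 0:
                miss = rng.random(len(features)) < config.metab_missing_rate
                values = np.where(miss, np.nan, values)
            data[sample] = values
    intensities = pd.DataFrame(data, index=pd.Index(features, name="feature"))
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    return intensities, metadata, planted


#: default tracing panel: TCA-cycle metabolites with their carbon counts and
#: per-state true m+2 fractions from a 13C-glucose tracer (chronic stimulation
#: D8C has depressed oxidative TCA labeling)
TRACING_PANEL: Tuple[Tuple[str, int], ...] = (
    ("fumarate", 4),
    ("malate", 4),
    ("aspartate", 4),
    ("citrate", 6),
    ("succinate", 4),
)
TRACING_M2_FRACTION: Dict[str, Dict[str, float]] = {
    "fumarate": {"D2": 0.30, "D8A": 0.28, "D8C": 0.12},
    "malate": {"D2": 0.30, "D8A": 0.27, "D8C": 0.12},
    "aspartate": {"D2": 0.25, "D8A": 0.23, "D8C": 0.10},
    "citrate": {"D2": 0.35, "D8A": 0.33, "D8C": 0.20},
    "succinate": {"D2": 0.28, "D8A": 0.26, "D8C": 0.14},
}


def simulate_tracing(
    config: SimulationConfig,
    panel: Sequence[Tuple[str, int]] = TRACING_PANEL,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Observed isotopologue intensities plus the true MIDs behind them.

    True MIDs put mass at m+0 and m+2 (oxidative TCA turns of a 13C-glucose
    tracer); observed intensities are the true MIDs convolved with binomial
    natural 13C abundance, scaled to a random total, and perturbed with
    Gaussian noise (sd ``tracer_noise_sd`` of the total).

    Returns ``(observed, true_mids)`` in long format with columns
    metabolite, condition, donor/``mass_shift``, intensities/fractions.
    """
    from .metabolomics import build_correction_matrix

    config.validate()
    rng = np.random.default_rng([config.seed, 4])
    observed_rows, true_rows = [], []
    for metabolite, n_carbons in panel:
        matrix = build_correction_matrix(n_carbons, p_nat=config.p_nat_13c)
        for cond in config.metab_conditions:
            m2 = TRACING_M2_FRACTION.get(metabolite, {}).get(cond, 0.2)
            true_mid = np.zeros(n_carbons + 1)
            true_mid[0] = 1.0 - m2
            true_mid[2] = m2
            for k, frac in enumerate(true_mid):
                true_rows.append(
                    {
                        "metabolite": metabolite,
                        "condition": cond,
                        "mass_shift": k,
                        "fraction": frac,
                    }
                )
            for donor in range(1, config.metab_n_donors + 1):
                total = float(np.power(2.0, rng.normal(20.0, 0.5)))
                expected = matrix @ true_mid
                noise = rng.normal(0.0, config.tracer_noise_sd, n_carbons + 1)
                obs = np.clip(expected + noise, 0.0, None) * total
                for k in range(n_carbons + 1):
                    observed_rows.append(
                        {
                            "metabolite": metabolite,
                            "condition": cond,
                            "donor": donor,
                            "n_carbons": n_carbons,
                            "mass_shift": k,
                            "intensity": obs[k],
                        }
                    )
    return pd.DataFrame(observed_rows), pd.DataFrame(true_rows)
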