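"""Cell-volume normalization and stable-isotope tracing corrections.

The profiled T cell states differ in cell size, so raw metabolite intensities
are divided by the total sampled biovolume (cell count x mean single-cell
volume, fL) before any comparison. For 13C tracing, observed isotopologue
intensities are corrected for natural 13C abundance by nonnegative least
squares against a binomial convolution matrix, yielding mass isotopologue
distributions (MIDs) whose m+k fractions are the reported labeling readouts.
Only carbon is corrected: the readouts of interest are carbon isotopologue
fractions, and H/N/O corrections would require formula-level metadata this
pipeline does not ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls


class MetabolomicsError(ValueError):
    """Invalid input to a metabolomics operation."""


# ---------------------------------------------------------------------------
# Cell-volume normalization
# ---------------------------------------------------------------------------

def normalize_cell_volume(
    intensities: pd.DataFrame,
    metadata: pd.DataFrame,
    mode: str = "biovolume",
) -> pd.DataFrame:
    """Divide each sample column by its total sampled biovolume.

    ``intensities`` is features x samples; ``metadata`` is indexed by sample
    with ``cell_count`` and ``mean_cell_volume`` (fL) columns. With
    ``mode="biovolume"`` (default) the divisor is cell_count x
    mean_cell_volume (units intensity * fL^-1); ``mode="volume"`` divides by
    the mean cell volume alone.
    """
    if mode not in {"biovolume", "volume"}:
        raise MetabolomicsError(f"unknown mode {mode!r}")
    out = intensities.copy()
    for sample in intensities.columns:
        if sample not in metadata.index:
            raise MetabolomicsError(f"sample {sample!r} missing from metadata")
        row = metadata.loc[sample]
        for col in ("cell_count", "mean_cell_volume"):
            if col not in metadata.columns or pd.isna(row[col]):
                raise MetabolomicsError(f"sample {sample!r}: missing metadata {col!r}")
        count = float(row["cell_count"])
        volume = float(row["mean_cell_volume"])
        if count <= 0 or volume <= 0:
            raise MetabolomicsError(
                f"sample {sample!r}: cell_count and mean_cell_volume must be > 0"
            )
        divisor = count * volume if mode == "biovolume" else volume
        out[sample] = intensities[sample] / divisor
    return out


# ---------------------------------------------------------------------------
# Natural-abundance correction
# ---------------------------------------------------------------------------

@dataclass
class MIDVector:
    """Mass isotopologue distribution of one metabolite (fractions m+0..m+n)."""

    metabolite: str
    carbon_count: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.fractions) != self.carbon_count + 1:
            raise MetabolomicsError(
                f"{self.metabolite}: expected {self.carbon_count + 1} fractions, "
                f"got {len(self.fractions)}"
            )


def build_correction_matrix(
    n_carbons: int,
    p_nat: float = 0.0107,
    tracer_purity: float = 1.0,
) -> np.ndarray:
    """Binomial natural-abundance convolution matrix for ``n_carbons``.

    Entry (i, j) is the probability that a molecule with j tracer-labeled
    carbons is observed at mass shift i: the j tracer positions each carry
    13C with probability ``tracer_purity`` and the remaining n-j positions
    with natural abundance ``p_nat``. Mass shifts beyond n are truncated, so
    columns sum to <= 1 (exactly 1 when no truncation occurs).
    """
    if n_carbons < 0:
        raise MetabolomicsError("n_carbons must be >= 0")
    for name, p in (("p_nat", p_nat), ("tracer_purity", tracer_purity)):
        if not 0.0 <= p <= 1.0:
            raise MetabolomicsError(f"{name} must be in [0, 1], got {p}")
    size = n_carbons + 1
    matrix = np.zeros((size, size))
    for j in range(size):
        nat = _binomial_pmf(n_carbons - j, p_nat)
        trc = _binomial_pmf(j, tracer_purity)
        col = np.convolve(trc, nat)
        matrix[:, j] = col[:size]
    return matrix


def _binomial_pmf(n: int, p: float) -> np.ndarray:
    from scipy.stats import binom

    return binom.pmf(np.arange(n + 1), n, p)


def correct_mid(
    observed: Sequence[float],
    matrix: np.ndarray,
    metabolite: str = "",
) -> MIDVector:
    """Natural-abundance-corrected MID from observed isotopologue intensities.

    Solves ``matrix @ x = observed`` under x >= 0 (nonnegative least
    squares; direct inversion can yield negative fractions under noise) and
    renormalizes x to sum to 1.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.ndim != 1 or len(observed) != matrix.shape[0]:
        raise MetabolomicsError(
            f"observed length {len(observed)} does not match matrix size {matrix.shape[0]}"
        )
    if np.all(observed == 0):
        raise MetabolomicsError("all-zero observation cannot be corrected")
    x, _residual = nnls(matrix, observed)
    total = x.sum()
    if total == 0:
        raise MetabolomicsError("correction produced an all-zero MID")
    return MIDVector(
        metabolite=metabolite, carbon_count=matrix.shape[0] - 1, fractions=x / total
    )


def label_fraction(mid: MIDVector, k: int) -> float:
    """Fraction of the metabolite at mass shift m+k."""
    if k < 0 or k > mid.carbon_count:
        raise MetabolomicsError(
            f"m+{k} out of range for a {mid.carbon_count}-carbon metabolite"
        )
    return float(mid.fractions[k])


def mean_enrichment(mid: MIDVector) -> float:
    """Carbon-weighted mean labeling: sum_k k * f_k / n."""
    if mid.carbon_count == 0:
        return 0.0
    ks = np.arange(mid.carbon_count + 1)
    return float(np.sum(ks * mid.fractions) / mid.carbon_count)


def correct_tracing_table(
    observed: pd.DataFrame,
    p_nat: float = 0.0107,
    tracer_purity: float = 1.0,
) -> pd.DataFrame:
    """Correct a long isotopologue table to MIDs per (metabolite, condition, donor).

    Expects columns metabolite, condition, donor, n_carbons, mass_shift,
    intensity. Returns the same keys with corrected ``fraction`` per mass
    shift.
    """
    required = {"metabolite", "condition", "donor", "n_carbons", "mass_shift", "intensity"}
    missing = required - set(observed.columns)
    if missing:
        raise MetabolomicsError(f"missing columns: {sorted(missing)}")
    rows = []
    keys = ["metabolite", "condition", "donor"]
    for (metabolite, condition, donor), group in observed.groupby(keys, sort=True):
        n_carbons = int(group["n_carbons"].iloc[0])
        vec = np.zeros(n_carbons + 1)
        for shift, intensity in zip(group["mass_shift"], group["intensity"]):
            vec[int(shift)] = float(intensity)
        mid = correct_mid(vec, build_correction_matrix(n_carbons, p_nat, tracer_purity),
                          metabolite=str(metabolite))
        for k, frac in enumerate(mid.fractions):
            rows.append(
                {
                    "metabolite": metabolite,
                    "condition": condition,
                    "donor": donor,
                    "mass_shift": k,
                    "fraction": frac,
                }
            )
    return pd.DataFrame(rows, columns=["metabolite", "condition", "donor", "mass_shift", "fraction"])
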