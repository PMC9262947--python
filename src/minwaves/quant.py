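"""Absolute protein quantification against a 15N-QconCAT internal standard.

Every measured peptide yields a light/heavy (14N sample / 15N QconCAT) peak
area ratio.  Two ribosomal core-protein peptides anchor the scale: their mean
ratio together with the known ribosome concentration of the expression
system gives the QconCAT concentration in the digest, after which each target
protein's concentration is its most C-terminal peptide's ratio times the
QconCAT concentration.  Technical replicates are averaged within each
biological replicate; the reported value is mean +- SD over biological
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PeptideMeasurement",
    "QuantResult",
    "light_heavy_ratio",
    "infer_qconcat_concentration",
    "protein_concentration",
    "quantify_table",
    "QconcatQuantifier",
]

TABLE_COLUMNS = (
    "protein",
    "peptide",
    "role",
    "light_area",
    "heavy_area",
    "bio_rep",
    "tech_rep",
)


@dataclass(frozen=True)
class PeptideMeasurement:
    """One peptide's light/heavy peak-area pair in one technical run."""

    protein: str
    peptide: str
    role: str  # "target" | "ribosomal_reference"
    light_area: float
    heavy_area: float
    biological_replicate: object = None
    technical_replicate: object = None


@dataclass
class QuantResult:
    """Absolute concentration of one protein (mean +- SD over biological
    replicates, technical replicates averaged first)."""

    protein: str
    concentration_uM: float
    sd_uM: float
    peptide_used: str
    n_technical: int
    n_biological: int
    below_detection: bool = False


def light_heavy_ratio(m: PeptideMeasurement) -> float:
    """Light/heavy peak area ratio; zero light area means below detection."""
    if m.heavy_area <= 0:
        raise ZeroDivisionError(
            f"heavy area is {m.heavy_area} for {m.protein}/{m.peptide}: "
            "unusable measurement"
        )
    return m.light_area / m.heavy_area


def infer_qconcat_concentration(
    ribo: list[PeptideMeasurement], ribo_conc_uM: float
) -> float:
    """QconCAT concentration from ribosomal reference peptides.

    ``qconcat = ribo_conc / mean(ribosomal light/heavy ratios)``, the mean
    taken over the reference peptides of one technical replicate.
    """
    if ribo_conc_uM <= 0:
        raise ValueError("ribo_conc_uM must be positive")
    if not ribo:
        raise ValueError("need >= 1 ribosomal reference measurement")
    ratios = [light_heavy_ratio(m) for m in ribo]
    mean_ratio = float(np.mean(ratios))
    if mean_ratio <= 0:
        raise ValueError("all ribosomal reference ratios are zero")
    return ribo_conc_uM / mean_ratio


def protein_concentration(
    target: list[PeptideMeasurement], qconcat_uM: float, cterm_peptide: str
) -> QuantResult:
    """Absolute concentration of one protein from its most C-terminal peptide.

    Per technical replicate the concentration is ``ratio * qconcat_uM`` (with
    the replicate-specific qconcat value supplied via a dict or a scalar);
    this helper takes a single scalar and is the building block used by
    :func:`quantify_table`, which handles per-replicate standards.
    """
    if qconcat_uM <= 0:
        raise ValueError("qconcat_uM must be positive")
    used = [m for m in target if m.peptide == cterm_peptide]
    if not used:
        available = sorted({m.peptide for m in target})
        raise ValueError(
            f"most C-terminal peptide {cterm_peptide!r} missing; available: {available}"
        )
    concs = np.array([light_heavy_ratio(m) * qconcat_uM for m in used])
    return QuantResult(
        protein=used[0].protein,
        concentration_uM=float(np.mean(concs)),
        sd_uM=float(np.std(concs, ddof=1)) if concs.size > 1 else 0.0,
        peptide_used=cterm_peptide,
        n_technical=len(used),
        n_biological=len({m.biological_replicate for m in used}),
        below_detection=bool(np.all(concs == 0)),
    )


def _check_table(table: pd.DataFrame) -> None:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    if (table["heavy_area"] <= 0).any():
        bad = table.loc[table["heavy_area"] <= 0, "peptide"].unique()
        raise ZeroDivisionError(f"non-positive heavy areas for peptides: {list(bad)}")


def quantify_table(
    table: pd.DataFrame,
    ribo_conc_uM: float,
    cterm_peptides: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every target protein in a tidy peak-area table.

    Parameters
    ----------
    table : DataFrame
        Columns ``protein, peptide, role, light_area, heavy_area, bio_rep,
        tech_rep``.
    ribo_conc_uM : float
        Ribosomal core-protein concentration of the expression system (uM);
        required, no default.
    cterm_peptides : dict
        Map protein -> its most C-terminal peptide label (the quantification
        peptide); other peptides of the protein are reported as a QC column,
        not averaged in.

    Returns
    -------
    (summary, per_replicate) : per-protein mean +- SD table over biological
    replicates, and the underlying per-(bio, tech) concentration table with a
    ``qc_other_peptides_uM`` column.
    """
    _check_table(table)
    if ribo_conc_uM <= 0:
        raise ValueError("ribo_conc_uM must be positive")
    table = table.copy()
    table["ratio"] = table["light_area"] / table["heavy_area"]

    refs = table[table["role"] == "ribosomal_reference"]
    if refs.empty:
        raise ValueError("no ribosomal reference measurements in table")
    qconcat = (
        refs.groupby(["bio_rep", "tech_rep"])["ratio"]
        .mean()
        .rename("ribo_ratio")
        .reset_index()
    )
    if (qconcat["ribo_ratio"] <= 0).any():
        raise ValueError("ribosomal reference ratios are zero in some replicate")
    qconcat["qconcat_uM"] = ribo_conc_uM / qconcat["ribo_ratio"]

    targets = table[table["role"] == "target"].merge(
        qconcat[["bio_rep", "tech_rep", "qconcat_uM"]], on=["bio_rep", "tech_rep"]
    )
    targets["conc_uM"] = targets["ratio"] * targets["qconcat_uM"]

    per_rep_rows = []
    summary_rows = []
    for protein, group in targets.groupby("protein", sort=False):
        if protein not in cterm_peptides:
            raise ValueError(f"no C-terminal peptide configured for {protein!r}")
        cterm = cterm_peptides[protein]
        main = group[group["peptide"] == cterm]
        if main.empty:
            available = sorted(group["peptide"].unique())
            raise ValueError(
                f"most C-terminal peptide {cterm!r} of {protein!r} missing; "
                f"available: {available}"
            )
        other = group[group["peptide"] != cterm]

        # technical replicates averaged within each biological replicate
        bio_means = main.groupby("bio_rep")["conc_uM"].mean()
        qc = other.groupby("bio_rep")["conc_uM"].mean() if not other.empty else None
        for bio, conc in bio_means.items():
            per_rep_rows.append(
                {
                    "protein": protein,
                    "bio_rep": bio,
                    "conc_uM": float(conc),
                    "n_technical": int((main["bio_rep"] == bio).sum()),
                    "qc_other_peptides_uM": float(qc[bio]) if qc is not None and bio in qc else np.nan,
                }
            )
        vals = bio_means.to_numpy(dtype=float)
        summary_rows.append(
            {
                "protein": protein,
                "concentration_uM": float(np.mean(vals)),
                "sd_uM": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                "peptide_used": cterm,
                "n_biological": int(vals.size),
                "n_technical": int(main.groupby("bio_rep")["tech_rep"].nunique().max()),
                "below_detection": bool(np.all(vals == 0)),
            }
        )
    return pd.DataFrame(summary_rows), pd.DataFrame(per_rep_rows)


class QconcatQuantifier(BaseEstimator):
    """QconCAT-referenced absolute quantifier (estimator facade over
    :func:`quantify_table`).

    Parameters
    ----------
    ribo_conc_uM : float
        Ribosomal core-protein concentration of the expression system (uM).
        Required; the value is system-specific and deliberately has no
        default.
    cterm_peptides : dict
        Protein -> most C-terminal peptide label.

    Attributes
    ----------
    results_ : DataFrame
        Per-protein summary (mean +- SD over biological replicates).
    per_replicate_ : DataFrame
        Per-biological-replicate concentrations with QC columns.
    """

    def __init__(self, ribo_conc_uM: float | None = None, cterm_peptides: dict | None = None):
        self.ribo_conc_uM = ribo_conc_uM
        self.cterm_peptides = cterm_peptides

    def fit(self, X: pd.DataFrame, y=None):
        if self.ribo_conc_uM is None:
            raise ValueError("ribo_conc_uM is required (no default exists)")
        if self.cterm_peptides is None:
            raise ValueError("cterm_peptides map is required")
        self.results_, self.per_replicate_ = quantify_table(
            X, self.ribo_conc_uM, self.cterm_peptides
        )
        return self

    def get_concentration(self, protein: str) -> float:
        row = self.results_[self.results_["protein"] == protein]
        if row.empty:
            raise KeyError(protein)
        return float(row["concentration_uM"].iloc[0])
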