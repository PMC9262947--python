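"""Synthetic light/heavy LC-MS peptide peak-area tables.

Emulates targeted quantification against a 15N-labeled QconCAT internal
standard: every tryptic peptide appears once as an unlabeled (14N, "light")
species from the expressed protein or the translation machinery, and once as
a labeled (15N, "heavy") species from the QconCAT.  The light/heavy area
ratio therefore equals the species concentration divided by the QconCAT
concentration, up to multiplicative measurement noise.

The peptide panel mirrors a typical QconCAT design for this system: two
peptides each for FtsA and MinD, one for MinE, and two ribosomal-core-protein
peptides serving as the concentration reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_peptide_table", "DEFAULT_CTERM_PEPTIDES", "PEPTIDE_PANEL"]

#: (protein, peptide label, role, is_cterm) — labels are opaque identifiers.
PEPTIDE_PANEL: tuple[tuple[str, str, str, bool], ...] = (
    ("FtsA", "FtsA_cterm", "target", True),
    ("FtsA", "FtsA_internal", "target", False),
    ("MinD", "MinD_cterm", "target", True),
    ("MinD", "MinD_internal", "target", False),
    ("MinE", "MinE_cterm", "target", True),
    ("Ribosome", "ribo_pep1", "ribosomal_reference", False),
    ("Ribosome", "ribo_pep2", "ribosomal_reference", False),
)

#: Most C-terminal peptide per target protein (the quantification peptide).
DEFAULT_CTERM_PEPTIDES: dict[str, str] = {
    p: pep for p, pep, role, cterm in PEPTIDE_PANEL if cterm
}

# Nominal heavy-channel peak area; actual areas are drawn around this scale so
# that tables exercise the analysis' scale invariance.
_HEAVY_AREA_SCALE = 1e6


def simulate_peptide_table(
    true_conc_uM: dict[str, float],
    ribo_conc_uM: float = 1.0,
    qconcat_conc_uM: float = 0.5,
    noise_cv: float = 0.0,
    n_biological: int = 3,
    n_technical: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a tidy peptide peak-area table.

    Parameters
    ----------
    true_conc_uM : dict
        Ground-truth concentration per target protein (uM); proteins absent
        from :data:`PEPTIDE_PANEL` are rejected.
    ribo_conc_uM : float
        Ribosomal core-protein concentration of the expression system (uM).
    qconcat_conc_uM : float
        Spiked QconCAT standard concentration (uM).
    noise_cv : float
        Coefficient of variation of the multiplicative lognormal noise on
        each light/heavy ratio; 0 gives exact ratios.

    Returns
    -------
    DataFrame with columns ``protein, peptide, role, light_area, heavy_area,
    bio_rep, tech_rep``.
    """
    if ribo_conc_uM <= 0 or qconcat_conc_uM <= 0:
        raise ValueError("concentrations must be positive")
    if any(c <= 0 for c in true_conc_uM.values()):
        raise ValueError("true concentrations must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    panel_proteins = {p for p, *_ in PEPTIDE_PANEL if p != "Ribosome"}
    unknown = set(true_conc_uM) - panel_proteins
    if unknown:
        raise ValueError(f"no peptides in the panel for: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        mu = -(sigma**2) / 2  # mean-one lognormal
    rows = []
    for bio in range(1, n_biological + 1):
        for tech in range(1, n_technical + 1):
            for protein, peptide, role, _ in PEPTIDE_PANEL:
                if role == "ribosomal_reference":
                    conc = ribo_conc_uM
                elif protein in true_conc_uM:
                    conc = true_conc_uM[protein]
                else:
                    continue
                ratio = conc / qconcat_conc_uM
                if noise_cv > 0:
                    ratio *= rng.lognormal(mu, sigma)
                heavy = _HEAVY_AREA_SCALE * rng.uniform(0.5, 2.0)
                rows.append(
                    {
                        "protein": protein,
                        "peptide": peptide,
                        "role": role,
                        "light_area": ratio * heavy,
                        "heavy_area": heavy,
                        "bio_rep": bio,
                        "tech_rep": tech,
                    }
                )
    return pd.DataFrame(rows)
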