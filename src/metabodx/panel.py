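"""Default 87-metabolite targeted panel.

The panel mirrors a targeted LC-MS/MS plasma assay covering acylcarnitines,
tryptophan catabolites (kynurenine, serotonin and indole routes), NO/urea-cycle
intermediates, proteinogenic amino acids and methionine/cystathionine-cycle
metabolites.  Baselines are order-of-magnitude plasma concentrations in µmol/L;
age slopes and case/control effects are the generative ground truth used by the
synthetic cohort generator, not measured values.

Each entry: (name, class_label, baseline µmol/L, age_slope %baseline/yr,
group_log2_effect).  A positive log2 effect means elevated in cases (IHD);
metabolites known to discriminate in this assay carry |log2 effect| = 1 with
the observed direction, all remaining analytes carry 0.
"""

from __future__ import annotations

ACYLCARNITINE = "acylcarnitine"
AMINO_ACID = "amino_acid"
TRYPTOPHAN = "tryptophan_pathway"
NO_UREA = "no_urea_cycle"
CYSTATHIONINE = "cystathionine_cycle"
OTHER = "other"

CLASS_LABELS = (ACYLCARNITINE, AMINO_ACID, TRYPTOPHAN, NO_UREA, CYSTATHIONINE, OTHER)

# Short assay codes for acylcarnitines as printed on targeted kits.
ALIASES: dict[str, str] = {
    "C0": "Carnitine",
    "C2": "Acetylcarnitine",
    "C3": "Propionylcarnitine",
    "C4": "Butyrylcarnitine",
    "C5": "Isovalerylcarnitine",
    "C5-DC": "Glutarylcarnitine",
    "C6": "Hexanoylcarnitine",
    "C6-DC": "Adipoylcarnitine",
    "C8": "Octanoylcarnitine",
    "C10": "Decanoylcarnitine",
    "C12": "Dodecanoylcarnitine",
    "C14": "Tetradecanoylcarnitine",
    "C14-OH": "Hydroxytetradecanoylcarnitine",
    "C16": "Palmitoylcarnitine",
    "C16-OH": "Hydroxyhexadecanoylcarnitine",
    "C16-1-OH": "Hydroxyhexadecenoylcarnitine",
    "ADMA": "Asymmetric dimethylarginine",
    "SDMA": "Symmetric dimethylarginine",
    "DMG": "Dimethylglycine",
    "Glu": "Glutamate",
    "Gln": "Glutamine",
    "Ser": "Serine",
    "Gly": "Glycine",
    "Val": "Valine",
    "Ile": "Isoleucine",
    "Leu": "Leucine",
    "Phe": "Phenylalanine",
    "Tyr": "Tyrosine",
}

# name, class, baseline, slope as fraction of baseline per year, log2 effect
_PANEL: list[tuple[str, str, float, float, float]] = [
    # --- acylcarnitine profiling (26) ---
    ("Carnitine", ACYLCARNITINE, 40.0, -0.004, -1.0),
    ("Acetylcarnitine", ACYLCARNITINE, 8.0, 0.002, 0.0),
    ("Propionylcarnitine", ACYLCARNITINE, 0.35, -0.004, -1.0),
    ("Butyrylcarnitine", ACYLCARNITINE, 0.25, 0.002, 0.0),
    ("Isovalerylcarnitine", ACYLCARNITINE, 0.12, -0.002, 0.0),
    ("Glutarylcarnitine", ACYLCARNITINE, 0.06, 0.004, -1.0),
    ("Hexanoylcarnitine", ACYLCARNITINE, 0.08, 0.0, 0.0),
    ("Adipoylcarnitine", ACYLCARNITINE, 0.05, 0.004, 1.0),
    ("Octanoylcarnitine", ACYLCARNITINE, 0.15, -0.002, 0.0),
    ("Octenoylcarnitine", ACYLCARNITINE, 0.05, 0.002, 0.0),
    ("Decanoylcarnitine", ACYLCARNITINE, 0.25, 0.0, 0.0),
    ("Decenoylcarnitine", ACYLCARNITINE, 0.1, 0.004, 0.0),
    ("Dodecanoylcarnitine", ACYLCARNITINE, 0.08, -0.004, 0.0),
    ("Tetradecanoylcarnitine", ACYLCARNITINE, 0.04, 0.002, 0.0),
    ("Tetradecenoylcarnitine", ACYLCARNITINE, 0.05, 0.0, 0.0),
    ("Hydroxytetradecanoylcarnitine", ACYLCARNITINE, 0.012, 0.006, 1.0),
    ("Hexadecenoylcarnitine", ACYLCARNITINE, 0.03, -0.002, 0.0),
    ("Palmitoylcarnitine", ACYLCARNITINE, 0.1, 0.004, 1.0),
    ("Hydroxyhexadecanoylcarnitine", ACYLCARNITINE, 0.015, 0.006, 1.0),
    ("Hydroxyhexadecenoylcarnitine", ACYLCARNITINE, 0.01, 0.004, 1.0),
    ("Stearoylcarnitine", ACYLCARNITINE, 0.06, 0.0, 0.0),
    ("Oleoylcarnitine", ACYLCARNITINE, 0.12, 0.002, 0.0),
    ("Linoleoylcarnitine", ACYLCARNITINE, 0.25, -0.002, 0.0),
    ("Hydroxybutyrylcarnitine", ACYLCARNITINE, 0.04, 0.002, 0.0),
    ("Hydroxyisovalerylcarnitine", ACYLCARNITINE, 0.03, 0.0, 0.0),
    ("Methylmalonylcarnitine", ACYLCARNITINE, 0.02, 0.004, 0.0),
    # --- tryptophan metabolism pathway (17) ---
    ("Tryptophan", TRYPTOPHAN, 60.0, -0.004, -1.0),
    ("Serotonin", TRYPTOPHAN, 0.6, 0.004, 1.0),
    ("Kynurenine", TRYPTOPHAN, 2.0, 0.006, 0.0),
    ("Kynurenic acid", TRYPTOPHAN, 0.05, 0.006, 1.0),
    ("Anthranilic acid", TRYPTOPHAN, 0.1, 0.004, 1.0),
    ("Xanthurenic acid", TRYPTOPHAN, 0.02, 0.004, 1.0),
    ("Quinolinic acid", TRYPTOPHAN, 0.4, 0.008, 0.0),
    ("3-Hydroxykynurenine", TRYPTOPHAN, 0.04, 0.002, 0.0),
    ("3-Hydroxyanthranilic acid", TRYPTOPHAN, 0.03, 0.0, 0.0),
    ("Indole-3-propionic acid", TRYPTOPHAN, 1.0, -0.004, -1.0),
    ("Indole-3-butyric acid", TRYPTOPHAN, 0.15, -0.002, -1.0),
    ("Indole-3-carboxaldehyde", TRYPTOPHAN, 0.1, -0.002, -1.0),
    ("Indole-3-acetic acid", TRYPTOPHAN, 1.5, 0.002, 0.0),
    ("Indole-3-lactic acid", TRYPTOPHAN, 0.5, 0.0, 0.0),
    ("Tryptamine", TRYPTOPHAN, 0.01, 0.0, 0.0),
    ("5-Hydroxyindoleacetic acid", TRYPTOPHAN, 0.05, 0.002, 0.0),
    ("Melatonin", TRYPTOPHAN, 0.0002, -0.004, 0.0),
    # --- NO / urea cycle (7) ---
    ("Asymmetric dimethylarginine", NO_UREA, 0.5, 0.004, -1.0),
    ("Symmetric dimethylarginine", NO_UREA, 0.5, 0.004, 0.0),
    ("Arginine", NO_UREA, 80.0, -0.002, -1.0),
    ("Citrulline", NO_UREA, 30.0, 0.006, -1.0),
    ("Ornithine", NO_UREA, 60.0, 0.002, 0.0),
    ("Homoarginine", NO_UREA, 2.0, -0.004, 0.0),
    ("Monomethylarginine", NO_UREA, 0.1, 0.0, 0.0),
    # --- amino acid profiling (24) ---
    ("Isoleucine", AMINO_ACID, 60.0, 0.002, 1.0),
    ("Leucine", AMINO_ACID, 120.0, 0.002, 1.0),
    ("Valine", AMINO_ACID, 220.0, 0.002, 0.0),
    ("Threonine", AMINO_ACID, 130.0, -0.004, -1.0),
    ("Histidine", AMINO_ACID, 80.0, -0.002, -1.0),
    ("Phenylalanine", AMINO_ACID, 60.0, 0.004, 1.0),
    ("Tyrosine", AMINO_ACID, 60.0, 0.002, -1.0),
    ("Proline", AMINO_ACID, 180.0, -0.002, -1.0),
    ("Lysine", AMINO_ACID, 170.0, -0.002, -1.0),
    ("Glycine", AMINO_ACID, 230.0, 0.002, -1.0),
    ("Serine", AMINO_ACID, 110.0, -0.002, 0.0),
    ("Alanine", AMINO_ACID, 380.0, 0.0, 0.0),
    ("Aspartic acid", AMINO_ACID, 10.0, -0.002, -1.0),
    ("Asparagine", AMINO_ACID, 50.0, -0.002, -1.0),
    ("Glutamate", AMINO_ACID, 60.0, 0.004, 0.0),
    ("Glutamine", AMINO_ACID, 550.0, -0.002, 0.0),
    ("3-Aminoisobutyric acid", AMINO_ACID, 2.0, 0.002, 1.0),
    ("Taurine", AMINO_ACID, 60.0, 0.0, 0.0),
    ("beta-Alanine", AMINO_ACID, 3.0, 0.002, 0.0),
    ("alpha-Aminobutyric acid", AMINO_ACID, 20.0, 0.0, 0.0),
    ("Sarcosine", AMINO_ACID, 1.5, 0.002, 0.0),
    ("Hydroxyproline", AMINO_ACID, 10.0, -0.004, 0.0),
    ("1-Methylhistidine", AMINO_ACID, 6.0, 0.0, 0.0),
    ("3-Methylhistidine", AMINO_ACID, 4.0, 0.002, 0.0),
    # --- cystathionine / methionine cycle (9) ---
    ("Methionine", CYSTATHIONINE, 25.0, -0.002, 1.0),
    ("Methionine sulfoxide", CYSTATHIONINE, 1.5, 0.004, -1.0),
    ("Cystathionine", CYSTATHIONINE, 0.15, 0.006, 1.0),
    ("Homocysteine", CYSTATHIONINE, 10.0, 0.006, 0.0),
    ("Cysteine", CYSTATHIONINE, 250.0, 0.002, 0.0),
    ("Dimethylglycine", CYSTATHIONINE, 3.0, 0.002, 1.0),
    ("Betaine", CYSTATHIONINE, 40.0, 0.0, 0.0),
    ("Choline", CYSTATHIONINE, 10.0, 0.002, 0.0),
    ("Norepinephrine", CYSTATHIONINE, 0.002, 0.004, -1.0),
    # --- other (4) ---
    ("Creatinine", OTHER, 80.0, 0.004, 0.0),
    ("Carnosine", OTHER, 0.5, -0.002, 0.0),
    ("Putrescine", OTHER, 0.1, 0.0, 0.0),
    ("Spermidine", OTHER, 0.15, 0.0, 0.0),
]

# The eleven-analyte diagnostic signature repeatedly selected across classifier
# families on this assay (GSG appears there as a ratio; its precursor glutamate
# stands in for it at the single-analyte level).
CONSENSUS_SIGNATURE: tuple[str, ...] = (
    "Norepinephrine",
    "Xanthurenic acid",
    "Anthranilic acid",
    "Serotonin",
    "Adipoylcarnitine",
    "Hydroxytetradecanoylcarnitine",
    "Palmitoylcarnitine",
    "Hydroxyhexadecanoylcarnitine",
    "Glutamate",
    "Phenylalanine",
    "Methionine",
)


def panel_class_map() -> dict[str, str]:
    """Metabolite name -> class label for the default panel."""
    return {name: cls for name, cls, _, _, _ in _PANEL}


def resolve_alias(name: str) -> str:
    """Map a short assay code (e.g. ``C16-OH``) to the full metabolite name.

    Matching is case- and surrounding-whitespace-insensitive; unknown names are
    returned stripped but otherwise untouched.
    """
    key = name.strip()
    lowered = {k.lower(): v for k, v in ALIASES.items()}
    return lowered.get(key.lower(), key)
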