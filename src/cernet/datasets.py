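"""Published group summaries from the emulated pig growth-rate study.

The two-group (high vs low growth rate, n = 4 per group) Duroc x Bama Xiang
crossbred design reported its phenotypes only as printed mean +/- SD tables
with significance letters.  Those printed summaries are first-class inputs
to the phenotype module, so they ship here as data: carcass and
meat-quality traits, serum biochemistry, muscle fiber diameter, and muscle
fiber-type proportions.  ``letter_high``/``letter_low`` are the printed
superscripts ("" where none was printed, i.e. a non-significant
difference).

SD values are taken at face value even where implausibly small (moisture
+/- 0.01, intramuscular fat +/- 0.008); the phenotype module flags the
resulting |t| > 50 comparisons as suspicious.
"""

from __future__ import annotations

import pandas as pd

_COLS = ["trait", "mean_high", "sd_high", "mean_low", "sd_low", "n", "letter_high", "letter_low"]

CARCASS_MEAT_QUALITY = pd.DataFrame(
    [
        ("live_weight_at_slaughter_kg", 148.38, 8.97, 88.75, 9.13, 4, "A", "B"),
        ("percentage_of_skin_fat_pct", 40.74, 6.02, 40.73, 2.80, 4, "", ""),
        ("percentage_of_lean_meat_pct", 44.05, 3.30, 43.17, 2.81, 4, "", ""),
        ("dressing_percentage_pct", 76.76, 1.09, 78.08, 3.46, 4, "", ""),
        ("loin_eye_area_cm2", 36.13, 6.07, 25.72, 4.90, 4, "a", "b"),
        ("backfat_middle_shoulder_mm", 57.83, 12.87, 58.83, 8.73, 4, "", ""),
        ("backfat_thoracolumbar_junction_mm", 29.27, 8.12, 35.58, 4.54, 4, "b", "a"),
        ("backfat_lumbar_sacral_junction_mm", 31.47, 11.07, 32.32, 2.57, 4, "", ""),
        ("ph_45min", 6.51, 0.10, 6.40, 0.24, 4, "", ""),
        ("ph_24h", 5.69, 0.04, 5.60, 0.14, 4, "a", "b"),
        ("meat_color_45min", 85.43, 2.45, 84.85, 2.55, 4, "", ""),
        ("meat_color_24h", 65.58, 5.30, 63.03, 6.38, 4, "", ""),
        ("colorimetric_score_45min", 3.50, 0.58, 3.00, 0.00, 4, "", ""),
        ("colorimetric_score_24h", 2.00, 0.00, 2.00, 0.00, 4, "", ""),
        ("drip_loss_48h_g", 0.54, 0.17, 0.48, 0.19, 4, "", ""),
        ("share_force_kgf", 7.82, 0.82, 7.95, 1.52, 4, "", ""),
        ("moisture_pct", 74.17, 0.01, 73.49, 0.01, 4, "", ""),
        ("imf_pct", 2.60, 0.008, 3.99, 0.015, 4, "b", "a"),
    ],
    columns=_COLS,
)

SERUM_BIOCHEMISTRY = pd.DataFrame(
    [
        ("total_protein_mg_ml", 31.20, 3.00, 36.23, 0.40, 4, "b", "a"),
        ("cholesterol_mmol_ml", 4.03, 0.47, 5.67, 0.92, 4, "b", "a"),
        ("triglycerides_mmol_ml", 0.86, 0.38, 1.21, 0.19, 4, "", ""),
        ("creatinine_umol_ml", 630.39, 69.83, 534.91, 72.98, 4, "", ""),
        ("glucose_mg_ml", 1.82, 0.17, 1.74, 0.33, 4, "", ""),
        ("urea_nitrogen_mmol_ml", 5.03, 1.60, 7.40, 0.55, 4, "", ""),
    ],
    columns=_COLS,
)

FIBER_DIAMETER = pd.DataFrame(
    [("muscle_fiber_diameter_um", 40.87, 3.85, 40.34, 5.68, 4, "", "")],
    columns=_COLS,
)

FIBER_TYPE = pd.DataFrame(
    [
        ("type_i_fibers_pct", 14.1, 1.61, 19.9, 1.18, 4, "b", "a"),
        ("type_ii_fibers_pct", 85.9, 4.77, 80.1, 5.30, 4, "a", "b"),
    ],
    columns=_COLS,
)


def printed_tables() -> dict:
    """All lettered summary tables keyed by a short name."""
    return {
        "carcass_meat_quality": CARCASS_MEAT_QUALITY.copy(),
        "serum_biochemistry": SERUM_BIOCHEMISTRY.copy(),
        "fiber_type": FIBER_TYPE.copy(),
    }


def letters_agree(printed_high: str, printed_low: str, p: float) -> bool:
    """Does a computed p-value reproduce a printed letter pattern?

    Different uppercase letters claim p < 0.01, different lowercase letters
    p < 0.05, and a shared letter or no letters claims p >= 0.05.
    """
    if printed_high == printed_low:
        return p >= 0.05
    if printed_high.isupper():
        return p < 0.01
    return p < 0.05
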