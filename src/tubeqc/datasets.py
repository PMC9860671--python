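"""Bundled reference dataset: a published quality-evaluation campaign
of evacuated citrate blood-collection tubes from three producers
(labelled A, B, C; labels carry the nominal draw volume in mL and the
expiration date as day.month.).

The tables carry the values at their reported precision: replicate
absorbances/concentrations of the within-day repeatability check,
six months of calibration-line parameters, the per-date tube-mass
summaries of the water-loss study for the two producer-B types, and
the composite-extraction and per-tube-fill determinations for the nine
examined tube types. They serve as worked-example input, as regression
fixtures, and as the desk-scale inputs the acceptance script
recomputes the headline results from.
"""

from __future__ import annotations

import pandas as pd

from .qc import CompositeDetermination, PerTubeDetermination, TubeSpec

__all__ = [
    "repeatability_table",
    "calibration_history",
    "mass_summaries",
    "tube_specs",
    "composite_results",
    "fill_results",
    "composite_determinations",
    "per_tube_determinations",
]

#: Flask volume (mL) of the composite extraction and the number of
#: tubes pooled per flask are campaign procedure constants.
COMPOSITE_FLASK_ML = 50.0
COMPOSITE_TUBES_PER_FLASK = 5


def repeatability_table() -> pd.DataFrame:
    """Ten within-day replicate determinations of a 14.12 mmol/L
    trisodium citrate stock (absorbance at 210 nm, 1-cm cuvette, and
    the concentration of the 10-fold diluted working solution)."""
    return pd.DataFrame(
        {
            "replicate": range(1, 11),
            "absorbance_210nm": [
                0.28716, 0.28839, 0.28825, 0.28799, 0.28860,
                0.28827, 0.28647, 0.28802, 0.28620, 0.28868,
            ],
            "concentration_mmol_L": [
                1.4118, 1.4178, 1.4171, 1.4159, 1.4189,
                1.4173, 1.4085, 1.4160, 1.4071, 1.4192,
            ],
        }
    )


def calibration_history() -> pd.DataFrame:
    """Six-point calibration line parameters (y = a*x + b) over a
    six-month within-laboratory reproducibility window."""
    rows = [
        ("2022-02-21", 0.1992, 0.0041, 0.0146, 0.0091, 0.0135, 0.99835),
        ("2022-02-25", 0.2032, 0.0010, 0.0002, 0.0021, 0.0032, 0.99991),
        ("2022-02-28", 0.2039, 0.0010, 0.0006, 0.0023, 0.0034, 0.99990),
        ("2022-03-11", 0.2021, 0.0006, -0.0004, 0.0013, 0.0019, 0.99997),
        ("2022-04-06", 0.2027, 0.0013, 0.0022, 0.0029, 0.0043, 0.99984),
        ("2022-05-05", 0.2032, 0.0028, 0.0055, 0.0064, 0.0094, 0.99922),
        ("2022-06-16", 0.2038, 0.0008, -0.0009, 0.0017, 0.0026, 0.99994),
        ("2022-07-07", 0.2021, 0.0005, 0.0018, 0.0011, 0.0016, 0.99998),
        ("2022-08-17", 0.2050, 0.0008, -0.0047, 0.0018, 0.0027, 0.99994),
    ]
    return pd.DataFrame(
        rows, columns=["date", "a", "s_a", "b", "s_b", "s_yx", "r_squared"]
    )


def mass_summaries() -> pd.DataFrame:
    """Per-date weighing summaries (n = 10 tubes per date) of the
    water-loss study for the two producer-B tube types that lost water.

    Columns: tube_type, date, count, sum, mean, variance (grams)."""
    rows = [
        ("B_1.8_31.7.", "25.02.", 10, 64.5799, 6.45799, 0.000517959),
        ("B_1.8_31.7.", "11.03.", 10, 64.3702, 6.43702, 0.000437162),
        ("B_1.8_31.7.", "06.04.", 10, 64.1965, 6.41965, 0.000752418),
        ("B_1.8_31.7.", "5.05.", 10, 63.8514, 6.38514, 0.000254645),
        ("B_1.8_31.7.", "16.06.", 10, 63.4715, 6.34715, 0.000271512),
        ("B_1.8_31.7.", "7.07.", 10, 63.4062, 6.34062, 0.000507422),
        ("B_3.6_31.8.", "25.02.", 10, 66.8741, 6.68741, 0.000588828),
        ("B_3.6_31.8.", "11.03.", 10, 66.6654, 6.66654, 0.000599349),
        ("B_3.6_31.8.", "06.04.", 10, 66.3714, 6.63714, 0.000796518),
        ("B_3.6_31.8.", "5.05.", 10, 66.1818, 6.61818, 0.000428091),
        ("B_3.6_31.8.", "16.06.", 10, 65.8877, 6.58877, 0.00035316),
        ("B_3.6_31.8.", "7.07.", 10, 65.5968, 6.55968, 0.000334517),
    ]
    return pd.DataFrame(
        rows, columns=["tube_type", "date", "count", "sum", "mean", "variance"]
    )


# label -> (nominal_conc mmol/L, V_ac_nom mL, V_draw_nom mL, buffered)
_SPECS = {
    "A_1.8_9.4.": (109.0, 0.2, 1.8, False),
    "A_1.8_9.7.": (109.0, 0.2, 1.8, False),
    "B_1.8_31.7.": (109.0, 0.2, 1.8, False),
    "C_1.8_31.3.": (109.0, 0.2, 1.8, True),
    "C_2.7_31.5.": (109.0, 0.3, 2.7, True),
    "B_3.6_31.8.": (129.0, 0.4, 3.6, False),
    "C_4.5_31.7.": (105.0, 0.5, 4.5, True),
    "C_4.5_31.12.": (105.0, 0.5, 4.5, True),
    "C_4.5_30.6.": (129.0, 0.5, 4.5, True),
}


def tube_specs() -> list[TubeSpec]:
    """Nominal declarations of the nine examined tube types."""
    return [
        TubeSpec(
            label=label,
            nominal_conc=c,
            nominal_ac_volume=v_ac,
            nominal_draw_volume=v_draw,
            buffered=buffered,
        )
        for label, (c, v_ac, v_draw, buffered) in _SPECS.items()
    ]


def composite_results() -> pd.DataFrame:
    """Composite-extraction campaign results per tube type: determined
    amount per tube and, as reported, the expected amount, relative
    bias and projected concentration at the nominal total volume."""
    rows = [
        ("A_1.8_9.4.", 109, 21.8, 26.3, 20.6, 13.2),
        ("A_1.8_9.7.", 109, 21.8, 26.8, 23.0, 13.4),
        ("B_1.8_31.7.", 109, 21.8, 23.6, 8.2, 11.8),
        ("C_1.8_31.3.", 109, 21.8, 26.8, 22.8, 13.4),
        ("C_2.7_31.5.", 109, 32.7, 38.4, 17.4, 12.8),
        ("B_3.6_31.8.", 129, 51.6, 56.3, 9.0, 14.1),
        ("C_4.5_31.7.", 105, 52.5, 55.0, 4.8, 11.0),
        ("C_4.5_31.12.", 105, 52.5, 56.1, 6.9, 11.2),
        ("C_4.5_30.6.", 129, 64.5, 66.6, 3.2, 13.3),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "nominal_conc_mmol_L",
            "expected_amount_umol",
            "determined_amount_umol",
            "amount_bias_pct",
            "conc_at_nominal_total_mmol_L",
        ],
    )


def fill_results() -> pd.DataFrame:
    """Per-tube-fill campaign results: concentration determined after
    adding water in the nominal draw volume, with the reported expected
    concentration, residual anticoagulant volume and biases."""
    rows = [
        ("A_1.8_9.4.", 1.8, 10.9, 13.6, 24.8, 0.2, 0.134, -33.1),
        ("A_1.8_9.7.", 1.8, 10.9, 13.7, 25.7, 0.2, 0.157, -21.6),
        ("B_1.8_31.7.", 1.8, 10.9, 13.0, 19.0, 0.2, 0.018, -91.1),
        ("C_1.8_31.3.", 1.8, 10.9, 14.8, 35.8, 0.2, 0.008, -95.9),
        ("C_2.7_31.5.", 2.7, 10.9, 13.4, 22.9, 0.3, 0.164, -45.3),
        ("B_3.6_31.8.", 3.6, 12.9, 14.3, 10.9, 0.4, 0.334, -16.6),
        ("C_4.5_31.7.", 4.5, 10.5, 12.1, 15.2, 0.5, 0.048, -90.4),
        ("C_4.5_31.12.", 4.5, 10.5, 12.1, 15.2, 0.5, 0.137, -72.6),
        ("C_4.5_30.6.", 4.5, 12.9, 14.1, 9.3, 0.5, 0.223, -55.5),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "draw_volume_mL",
            "expected_conc_mmol_L",
            "determined_conc_mmol_L",
            "conc_bias_pct",
            "nominal_ac_volume_mL",
            "ac_volume_mL",
            "ac_volume_bias_pct",
        ],
    )


def composite_determinations() -> dict[str, CompositeDetermination]:
    """The campaign's composite determinations as typed records.

    The flask concentration is reconstructed from the reported amount
    per tube and the procedure constants (50-mL flask, 5 tubes), which
    inverts the amount equation exactly.
    """
    return {
        row.label: CompositeDetermination(
            concentration=row.determined_amount_umol
            * COMPOSITE_TUBES_PER_FLASK
            / COMPOSITE_FLASK_ML,
            flask_volume=COMPOSITE_FLASK_ML,
            tube_count=COMPOSITE_TUBES_PER_FLASK,
        )
        for row in composite_results().itertuples()
    }


def per_tube_determinations() -> dict[str, PerTubeDetermination]:
    """The campaign's per-tube fill determinations as typed records."""
    return {
        row.label: PerTubeDetermination(
            concentration=row.determined_conc_mmol_L,
            added_volume=row.draw_volume_mL,
        )
        for row in fill_results().itertuples()
    }
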