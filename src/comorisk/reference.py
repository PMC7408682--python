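"""Published reference values from the Korean cancer-screenee cohort study.

This module stores, as plain data, the quantities the source study printed
and that the rest of the package either consumes as inputs (the regularized
partial-correlation network of the 16 food groups, the daily-intake
marginals, the marker-category prevalences, the integer risk-point tables)
or validates against (the fully adjusted hazard ratios per comorbidity
category).  Values are transcribed at the printed precision (two decimals
for network edges and hazard ratios).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Food groups in the published order.
FOOD_GROUPS: list[str] = [
    "cereals_grains",
    "potatoes_starches",
    "sugars_sweets",
    "legumes",
    "seeds_nuts",
    "vegetables",
    "mushrooms",
    "fruits",
    "meat_poultry",
    "eggs",
    "fish_shellfish",
    "seaweed",
    "milk_dairy",
    "oils_fats",
    "beverages",
    "seasonings",
]

FOOD_GROUP_NAMES: dict[str, str] = {
    "cereals_grains": "Cereals and grains",
    "potatoes_starches": "Potatoes and starches",
    "sugars_sweets": "Sugars and sweets",
    "legumes": "Legumes",
    "seeds_nuts": "Seeds and nuts",
    "vegetables": "Vegetables",
    "mushrooms": "Mushrooms",
    "fruits": "Fruits",
    "meat_poultry": "Meat and poultry",
    "eggs": "Eggs",
    "fish_shellfish": "Fish and shellfish",
    "seaweed": "Seaweed",
    "milk_dairy": "Milk and dairy",
    "oils_fats": "Oils and fats",
    "beverages": "Beverages",
    "seasonings": "Seasonings",
}

#: Nonzero regularized partial correlations of the published dietary network
#: (lower triangle; absent pairs were shrunk to exactly zero by the
#: graphical-lasso penalty).
NETWORK_EDGES: dict[tuple[str, str], float] = {
    ("sugars_sweets", "potatoes_starches"): 0.05,
    ("legumes", "potatoes_starches"): 0.22,
    ("seeds_nuts", "cereals_grains"): -0.08,
    ("seeds_nuts", "potatoes_starches"): 0.05,
    ("seeds_nuts", "sugars_sweets"): 0.05,
    ("seeds_nuts", "legumes"): 0.08,
    ("vegetables", "cereals_grains"): 0.08,
    ("mushrooms", "cereals_grains"): -0.05,
    ("mushrooms", "sugars_sweets"): -0.12,
    ("mushrooms", "legumes"): 0.07,
    ("mushrooms", "seeds_nuts"): 0.12,
    ("mushrooms", "vegetables"): 0.18,
    ("fruits", "cereals_grains"): -0.07,
    ("fruits", "sugars_sweets"): 0.04,
    ("fruits", "legumes"): -0.08,
    ("fruits", "seeds_nuts"): 0.08,
    ("fruits", "vegetables"): 0.08,
    ("meat_poultry", "cereals_grains"): 0.11,
    ("meat_poultry", "potatoes_starches"): -0.05,
    ("meat_poultry", "legumes"): -0.04,
    ("meat_poultry", "vegetables"): -0.07,
    ("meat_poultry", "mushrooms"): 0.05,
    ("meat_poultry", "fruits"): 0.15,
    ("eggs", "legumes"): -0.07,
    ("eggs", "seeds_nuts"): 0.09,
    ("eggs", "fruits"): 0.06,
    ("eggs", "meat_poultry"): 0.17,
    ("fish_shellfish", "potatoes_starches"): 0.08,
    ("fish_shellfish", "legumes"): 0.09,
    ("fish_shellfish", "seeds_nuts"): 0.06,
    ("fish_shellfish", "vegetables"): 0.10,
    ("fish_shellfish", "mushrooms"): 0.15,
    ("fish_shellfish", "meat_poultry"): 0.23,
    ("seaweed", "potatoes_starches"): 0.04,
    ("seaweed", "legumes"): 0.10,
    ("seaweed", "vegetables"): 0.23,
    ("seaweed", "mushrooms"): 0.07,
    ("seaweed", "fruits"): 0.06,
    ("seaweed", "meat_poultry"): -0.06,
    ("seaweed", "fish_shellfish"): 0.19,
    ("milk_dairy", "cereals_grains"): -0.09,
    ("milk_dairy", "sugars_sweets"): 0.05,
    ("milk_dairy", "seeds_nuts"): 0.07,
    ("milk_dairy", "fruits"): 0.18,
    ("milk_dairy", "eggs"): 0.12,
    ("oils_fats", "cereals_grains"): 0.07,
    ("oils_fats", "sugars_sweets"): 0.70,
    ("oils_fats", "seeds_nuts"): -0.05,
    ("oils_fats", "mushrooms"): 0.12,
    ("oils_fats", "fruits"): -0.08,
    ("oils_fats", "meat_poultry"): 0.20,
    ("oils_fats", "eggs"): 0.08,
    ("oils_fats", "seaweed"): -0.05,
    ("oils_fats", "milk_dairy"): -0.04,
    ("beverages", "sugars_sweets"): 0.08,
    ("beverages", "mushrooms"): 0.05,
    ("beverages", "fruits"): 0.08,
    ("beverages", "meat_poultry"): 0.10,
    ("beverages", "fish_shellfish"): 0.10,
    ("beverages", "milk_dairy"): 0.08,
    ("seasonings", "potatoes_starches"): 0.37,
    ("seasonings", "legumes"): 0.23,
    ("seasonings", "seeds_nuts"): 0.06,
    ("seasonings", "vegetables"): 0.34,
    ("seasonings", "fruits"): 0.19,
    ("seasonings", "meat_poultry"): 0.07,
    ("seasonings", "eggs"): 0.04,
    ("seasonings", "fish_shellfish"): 0.11,
    ("seasonings", "oils_fats"): 0.05,
}


def reference_network_matrix() -> pd.DataFrame:
    """Published 16x16 symmetric partial-correlation matrix (zero diagonal)."""
    idx = {g: i for i, g in enumerate(FOOD_GROUPS)}
    mat = np.zeros((16, 16))
    for (a, b), rho in NETWORK_EDGES.items():
        mat[idx[a], idx[b]] = rho
        mat[idx[b], idx[a]] = rho
    return pd.DataFrame(mat, index=FOOD_GROUPS, columns=FOOD_GROUPS)


#: Daily intake mean and standard deviation per food group (g/day), full cohort.
INTAKE_MEAN_SD: dict[str, tuple[float, float]] = {
    "cereals_grains": (582.77, 213.71),
    "potatoes_starches": (44.49, 43.74),
    "sugars_sweets": (5.02, 5.24),
    "legumes": (59.84, 67.42),
    "seeds_nuts": (5.52, 9.98),
    "vegetables": (312.12, 204.07),
    "mushrooms": (9.05, 13.48),
    "fruits": (220.65, 255.47),
    "meat_poultry": (58.62, 51.63),
    "eggs": (17.33, 18.04),
    "fish_shellfish": (39.99, 34.98),
    "seaweed": (2.25, 2.37),
    "milk_dairy": (108.63, 137.91),
    "oils_fats": (3.83, 3.81),
    "beverages": (75.15, 110.42),
    "seasonings": (17.42, 14.80),
}

#: Published max-normalized eigenvector centralities (for validation only;
#: the package recomputes these from the network).
PUBLISHED_CENTRALITY: dict[str, float] = {
    "cereals_grains": 0.09,
    "potatoes_starches": 0.68,
    "sugars_sweets": 0.51,
    "legumes": 0.59,
    "seeds_nuts": 0.32,
    "vegetables": 0.76,
    "mushrooms": 0.50,
    "fruits": 0.27,
    "meat_poultry": 0.48,
    "eggs": 0.30,
    "fish_shellfish": 0.70,
    "seaweed": 0.45,
    "milk_dairy": 0.13,
    "oils_fats": 0.61,
    "beverages": 0.25,
    "seasonings": 1.00,
}

# ---------------------------------------------------------------------------
# Comorbidity markers

MARKERS = ("blood_pressure", "cholesterol", "glucose", "gfr")

#: Category counts in the analysis cohort (N = 5606); normalized copies serve
#: as the synthetic generator's default category mixture.
MARKER_CATEGORY_COUNTS: dict[str, dict[str, int]] = {
    "blood_pressure": {"normal": 1662, "elevated": 2225, "hypertension": 1719},
    "cholesterol": {"low": 1492, "normal": 1141, "elevated": 2793},
    "glucose": {"normal": 5029, "prediabetes_diabetes": 577},
    "gfr": {"lt60": 268, "b60_89": 4459, "ge90": 739},
}


def marker_prevalences() -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for marker, counts in MARKER_CATEGORY_COUNTS.items():
        total = sum(counts.values())
        out[marker] = {cat: n / total for cat, n in counts.items()}
    return out


#: Published integer risk points per comorbidity category (main analysis;
#: reference categories carry 0).
RISK_POINTS_MAIN: dict[str, dict[str, int]] = {
    "blood_pressure": {"normal": 0, "elevated": 2, "hypertension": 8},
    "cholesterol": {"elevated": 0, "low": 5, "normal": 8},
    "glucose": {"normal": 0, "prediabetes_diabetes": 5},
    "gfr": {"lt60": 0, "b60_89": 2, "ge90": 9},
}

#: Sensitivity variant with total cholesterol removed from the score.
RISK_POINTS_NO_CHOLESTEROL: dict[str, dict[str, int]] = {
    "blood_pressure": {"normal": 0, "elevated": 2, "hypertension": 8},
    "glucose": {"normal": 0, "prediabetes_diabetes": 5},
    "gfr": {"lt60": 0, "b60_89": 2, "ge90": 10},
}

#: Fully adjusted hazard ratios per non-reference category (main analysis),
#: used by the age-coefficient consistency scan.
FULLY_ADJUSTED_HR: dict[tuple[str, str], float] = {
    ("blood_pressure", "elevated"): 1.12,
    ("blood_pressure", "hypertension"): 1.56,
    ("cholesterol", "low"): 1.31,
    ("cholesterol", "normal"): 1.51,
    ("glucose", "prediabetes_diabetes"): 1.32,
    ("gfr", "b60_89"): 1.11,
    ("gfr", "ge90"): 1.65,
}

#: Default per-year log-hazard of age.  Not printed by the source study;
#: chosen because round(ln(HR)/0.0556) reproduces 6 of the 7 published points
#: (the seventh misses by one from two-decimal HR rounding).
DEFAULT_BETA_AGE: float = 0.0556

# ---------------------------------------------------------------------------
# Score strata (label, low, high) with inclusive integer bounds.

STRATA_MAIN: list[tuple[str, int, int]] = [
    ("0-8", 0, 8),
    ("9-10", 9, 10),
    ("11-15", 11, 15),
    ("16-30", 16, 30),
]

STRATA_NO_CHOLESTEROL: list[tuple[str, int, int]] = [
    ("0-2", 0, 2),
    ("3-8", 3, 8),
    ("9-10", 9, 10),
    ("11-23", 11, 23),
]

STRATA_EARLY_INCLUDED: list[tuple[str, int, int]] = [
    ("0-4", 0, 4),
    ("5-8", 5, 8),
    ("9-10", 9, 10),
    ("11-24", 11, 24),
]
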