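"""Antidepressant product classification.

Products map to one of three mutually exclusive classes by proposed method of
action: ``SSRI`` (selective serotonin reuptake inhibitors), ``TCA``
(tricyclics) and ``OTHER`` (chiefly mirtazapine and venlafaxine).  The
packaged dictionary (``data/antidepressants.csv``) covers the generics used
by the synthetic generator and is a plain two-column CSV the user can edit or
replace; unknown products always raise, they are never silently dropped.

Also provides the low-dose amitriptyline flag (<75 mg/day) used by the
sensitivity analysis, since amitriptyline at such doses is commonly
prescribed for pain rather than depression.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DRUG_CLASSES",
    "UnknownProductError",
    "ProductDictionary",
    "classify_product",
    "classify_table",
    "flag_low_dose_amitriptyline",
]

DRUG_CLASSES = ("SSRI", "TCA", "OTHER")

LOW_DOSE_AMITRIPTYLINE_MG = 75.0  # strict: flagged only when dose < 75 mg/day


class UnknownProductError(KeyError):
    """A product name that the dictionary cannot classify."""

    def __init__(self, names: Iterable[str]):
        self.names = sorted(set(names))
        super().__init__(f"unclassified product(s): {', '.join(self.names)}")


class ProductDictionary:
    """Case-insensitive product-name -> drug-class lookup."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map: dict[str, str] = {}
        for name, cls in mapping.items():
            cls = str(cls).strip().upper()
            if cls not in DRUG_CLASSES:
                raise ValueError(f"unknown drug class {cls!r} for product {name!r}")
            self._map[str(name).strip().lower()] = cls

    @classmethod
    def from_csv(cls, path) -> "ProductDictionary":
        df = pd.read_csv(path)
        missing = {"product_name", "drug_class"} - set(df.columns)
        if missing:
            raise ValueError(f"product dictionary missing column(s): {sorted(missing)}")
        return cls(dict(zip(df["product_name"], df["drug_class"])))

    @classmethod
    def packaged(cls) -> "ProductDictionary":
        """The dictionary shipped with the package."""
        ref = resources.files("adtrends").joinpath("data/antidepressants.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def __contains__(self, name: str) -> bool:
        return str(name).strip().lower() in self._map

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, name: str) -> str:
        key = str(name).strip().lower()
        if not key:
            raise ValueError("empty product name")
        try:
            return self._map[key]
        except KeyError:
            raise UnknownProductError([name]) from None

    def items(self):
        return self._map.items()


def classify_product(product_name: str, dictionary: ProductDictionary | None = None) -> str:
    """Return the drug class of ``product_name`` (case-insensitive).

    Raises :class:`UnknownProductError` for products absent from the
    dictionary.
    """
    if dictionary is None:
        dictionary = ProductDictionary.packaged()
    return dictionary.lookup(product_name)


def classify_table(
    therapy: pd.DataFrame, dictionary: ProductDictionary | None = None
) -> pd.DataFrame:
    """Attach a ``drug_class`` column to a therapy table.

    Every distinct product name must resolve; otherwise all unknown names are
    reported together in one :class:`UnknownProductError`.
    """
    if dictionary is None:
        dictionary = ProductDictionary.packaged()
    out = therapy.copy()
    if out.empty:
        out["drug_class"] = pd.Series(dtype=object)
        return out
    keys = out["product_name"].astype(str).str.strip().str.lower()
    lut = dict(dictionary.items())
    classes = keys.map(lut)
    if classes.isna().any():
        raise UnknownProductError(out.loc[classes.isna(), "product_name"].unique())
    out["drug_class"] = classes
    return out


def flag_low_dose_amitriptyline(product_name: str, daily_dose_mg: float | None) -> bool:
    """True iff the prescription is amitriptyline at a known dose below 75 mg/day.

    A missing dose is never flagged: in the sensitivity analysis those
    prescriptions are retained (the conservative choice, since no imputation
    rule for the dose threshold is defined).
    """
    if str(product_name).strip().lower() != "amitriptyline":
        return False
    if daily_dose_mg is None or pd.isna(daily_dose_mg):
        return False
    return float(daily_dose_mg) < LOW_DOSE_AMITRIPTYLINE_MG


def flag_low_dose_table(therapy: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`flag_low_dose_amitriptyline` over a therapy table."""
    name = therapy["product_name"].astype(str).str.strip().str.lower()
    dose = pd.to_numeric(therapy["daily_dose_mg"], errors="coerce")
    return (name == "amitriptyline") & dose.notna() & (dose < LOW_DOSE_AMITRIPTYLINE_MG)
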