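"""Derived glycan traits.

A derived trait summarises structurally related chromatogram peaks (e.g.
antennary fucosylation, low branching) as (sum of numerator peaks) / (sum of
denominator peaks) on the relative-abundance scale, proxying the activity of
the glycosyltransferases responsible for the shared feature.  Definitions are
declarative and overridable; the shipped default file holds 16 traits built
from the packaged peak-structure annotation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .preprocess import PEAKS, NormalizedGlycome


@dataclass(frozen=True)
class DerivedTraitSpec:
    trait_name: str
    numerator_peaks: tuple
    denominator_peaks: tuple | None = None  # None -> all peaks

    def validate(self, universe=PEAKS) -> None:
        if not self.numerator_peaks:
            raise ValueError(f"trait {self.trait_name}: empty numerator")
        universe = set(universe)
        for p in self.numerator_peaks:
            if p not in universe:
                raise ValueError(f"trait {self.trait_name}: unknown peak {p!r}")
        if self.denominator_peaks is not None:
            for p in self.denominator_peaks:
                if p not in universe:
                    raise ValueError(f"trait {self.trait_name}: unknown peak {p!r}")
            if not set(self.numerator_peaks) <= set(self.denominator_peaks):
                raise ValueError(
                    f"trait {self.trait_name}: numerator must be a subset of denominator"
                )


def _parse_specs(entries, universe) -> list:
    specs, seen = [], set()
    for entry in entries:
        name = entry["name"]
        if name in seen:
            raise ValueError(f"duplicate trait name {name!r}")
        seen.add(name)
        denom = entry.get("denominator", "all")
        spec = DerivedTraitSpec(
            trait_name=name,
            numerator_peaks=tuple(entry["numerator"]),
            denominator_peaks=None if denom in (None, "all") else tuple(denom),
        )
        spec.validate(universe)
        specs.append(spec)
    return specs


def load_trait_spec(path, universe=PEAKS) -> list:
    """Load and validate trait definitions from a YAML/JSON list."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return _parse_specs(entries, universe)


def default_trait_specs(universe=PEAKS) -> list:
    """The 16 shipped default traits."""
    ref = importlib.resources.files("glycoresponse.data").joinpath("derived_traits.yaml")
    entries = yaml.safe_load(ref.read_text())
    return _parse_specs(entries, universe)


def load_peak_annotation() -> pd.DataFrame:
    ref = importlib.resources.files("glycoresponse.data").joinpath("peak_annotation.tsv")
    import io

    return pd.read_csv(io.StringIO(ref.read_text()), sep="\t", comment="#")


def compute_traits(g: NormalizedGlycome, specs) -> pd.DataFrame:
    """Trait table (samples x traits) from relative abundances.

    A zero denominator yields a missing value with a warning.
    """
    g._require("relative")
    out = {}
    for spec in specs:
        num = g.values[list(spec.numerator_peaks)].sum(axis=1)
        if spec.denominator_peaks is None:
            den = g.values.sum(axis=1)
        else:
            den = g.values[list(spec.denominator_peaks)].sum(axis=1)
        zero = den == 0
        if zero.any():
            import warnings

            warnings.warn(f"trait {spec.trait_name}: zero denominator for {int(zero.sum())} samples")
        out[spec.trait_name] = np.where(zero, np.nan, num / den.replace(0, np.nan))
    return pd.DataFrame(out, index=g.values.index)
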