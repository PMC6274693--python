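"""Hypothetical mixture descriptors: toxic-unit-fraction-weighted sums.

Under concentration addition, a binary mixture is represented by the
component-wise convex combination of its components' descriptors,

    D_mix = x_a * D_a + x_b * D_b,

with x the toxic-unit fractions (x_a + x_b = 1). The weighted triple-bond
count is kept as a real number; nothing is rounded.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .chem_descriptors import DESCRIPTOR_NAMES, DescriptorVector
from .errors import DataLoadError, ValidationError

_FRACTION_TOL = 1e-9

MIXTURE_COLUMNS = ("ntb_mix", "acic2_mix", "qmaxc_mix")


def hypothetical_descriptor(
    components: Sequence[DescriptorVector],
    fractions: Sequence[float],
) -> DescriptorVector:
    """Weighted sum of component descriptor vectors.

    Fractions must be nonnegative and sum to 1 (within 1e-9). Generalizes to
    any number of components; the bundled data exercises the binary case.
    """
    if len(components) != len(fractions):
        raise ValidationError("one fraction per component required")
    fr = np.asarray(fractions, dtype=float)
    if (fr < 0).any():
        raise ValidationError(f"fractions must be nonnegative: {fr.tolist()}")
    if abs(fr.sum() - 1.0) > _FRACTION_TOL:
        raise ValidationError(f"fractions must sum to 1, got {fr.sum()!r}")
    stacked = np.stack([c.as_array() for c in components])
    mixed = fr @ stacked
    return DescriptorVector(*mixed)


def build_mixture_matrix(
    mixtures: pd.DataFrame, descriptors: pd.DataFrame
) -> pd.DataFrame:
    """One hypothetical-descriptor row per mixture.

    Columns are fixed in the order (ntb_mix, acic2_mix, qmaxc_mix), followed
    by the provenance columns (component ids and fractions).
    """
    table = descriptors.set_index("id")
    referenced = set(mixtures["component_a"]) | set(mixtures["component_b"])
    missing = sorted(referenced - set(table.index))
    if missing:
        raise DataLoadError(f"no descriptor row for compound(s): {missing}")

    rows = []
    for rec in mixtures.itertuples():
        d_a = DescriptorVector(*table.loc[rec.component_a, list(DESCRIPTOR_NAMES)])
        d_b = DescriptorVector(*table.loc[rec.component_b, list(DESCRIPTOR_NAMES)])
        mixed = hypothetical_descriptor([d_a, d_b], [rec.fraction_a, rec.fraction_b])
        rows.append({
            "combo_id": rec.combo_id,
            "ntb_mix": mixed.ntb,
            "acic2_mix": mixed.acic2,
            "qmaxc_mix": mixed.qmaxc,
            "component_a": rec.component_a,
            "component_b": rec.component_b,
            "fraction_a": rec.fraction_a,
            "fraction_b": rec.fraction_b,
        })
    return pd.DataFrame(rows)
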