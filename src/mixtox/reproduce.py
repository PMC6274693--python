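"""Recompute the published headline statistics from the bundled tables.

The source tables print experimental AND model-predicted activities for
every compound and mixture, so the reported model statistics are
recomputable at desk scale directly from those columns. Each check pairs a
recomputed value with the published one and a tolerance absorbing the
two-decimal rounding of the printed columns.

RMS conventions per model family (see the methods note): the linear-model
statistics use the standard error of estimate sqrt(SSE/(N−p−1)) with p=3
descriptors; the RBF-network statistics use the plain sqrt(SSE/N).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataset_io import load_compound_table, load_mixture_table
from .validation import golbraikh_tropsha, r_squared, rms, vif

#: Published pairwise correlations between the three model descriptors.
DESCRIPTOR_CORRELATIONS = {
    ("acic2", "ntb"): -0.314,
    ("acic2", "qmaxc"): 0.740,
    ("ntb", "qmaxc"): 0.013,
}


@dataclass
class Check:
    id: str
    computed: float
    printed: float
    tol: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.printed) <= self.tol


def headline_statistics() -> dict[str, float]:
    """Every desk-scale statistic recomputable from the bundled tables."""
    compounds = load_compound_table()
    mixtures = load_mixture_table(compounds=compounds)
    train = mixtures[mixtures.subset != "T"]
    test = mixtures[mixtures.subset == "T"]

    gt = golbraikh_tropsha(test.neg_log_ec50mix_exp, test.mlr_pred)
    stats = {
        "r2_mlr_train": r_squared(train.neg_log_ec50mix_exp, train.mlr_pred),
        "r2_mlr_test": r_squared(test.neg_log_ec50mix_exp, test.mlr_pred),
        "r2_rbfnn_train": r_squared(train.neg_log_ec50mix_exp, train.rbfnn_pred),
        "r2_rbfnn_test": r_squared(test.neg_log_ec50mix_exp, test.rbfnn_pred),
        "r2_single": r_squared(compounds.neg_log_ec50_exp, compounds.neg_log_ec50_pred),
        "rms_mlr_train": rms(train.neg_log_ec50mix_exp, train.mlr_pred, ddof=4),
        "rms_mlr_test": rms(test.neg_log_ec50mix_exp, test.mlr_pred, ddof=4),
        "rms_single": rms(compounds.neg_log_ec50_exp, compounds.neg_log_ec50_pred, ddof=4),
        "rms_rbfnn_train": rms(train.neg_log_ec50mix_exp, train.rbfnn_pred),
        "rms_rbfnn_test": rms(test.neg_log_ec50mix_exp, test.rbfnn_pred),
        "k_mlr_test": gt.k,
        "k_prime_mlr_test": gt.k_prime,
        "r0_sq_mlr_test": gt.r0_sq,
        "r0_ratio_mlr_test": (gt.r2 - gt.r0_sq) / gt.r2,
    }
    for (a, b), r in DESCRIPTOR_CORRELATIONS.items():
        stats[f"vif_{a}_{b}"] = vif(r)
    return stats


def reference_checks() -> list[Check]:
    """Recomputed statistics paired with their published values."""
    s = headline_statistics()
    r2_tol, rms_tol, k_tol, vif_tol = 0.005, 0.01, 0.01, 0.0005
    return [
        Check("r2_mlr_train", s["r2_mlr_train"], 0.869, r2_tol),
        Check("r2_mlr_test", s["r2_mlr_test"], 0.853, r2_tol),
        Check("r2_rbfnn_train", s["r2_rbfnn_train"], 0.925, r2_tol),
        Check("r2_rbfnn_test", s["r2_rbfnn_test"], 0.896, r2_tol),
        Check("r2_single", s["r2_single"], 0.736, r2_tol),
        Check("rms_mlr_train", s["rms_mlr_train"], 0.599, rms_tol),
        Check("rms_mlr_test", s["rms_mlr_test"], 0.691, rms_tol),
        Check("rms_single", s["rms_single"], 1.042, rms_tol),
        Check("rms_rbfnn_train", s["rms_rbfnn_train"], 0.447, rms_tol),
        Check("rms_rbfnn_test", s["rms_rbfnn_test"], 0.547, rms_tol),
        Check("k_mlr_test", s["k_mlr_test"], 0.983, k_tol),
        Check("vif_acic2_qmaxc", s["vif_acic2_qmaxc"], 2.210, vif_tol),
        Check("vif_acic2_ntb", s["vif_acic2_ntb"], 1.109, vif_tol),
    ]


def checks_frame(only: str | None = None) -> pd.DataFrame:
    checks = reference_checks()
    if only is not None:
        checks = [c for c in checks if c.id == only]
        if not checks:
            raise KeyError(f"unknown check id {only!r}")
    return pd.DataFrame(
        [{"id": c.id, "computed": c.computed, "printed": c.printed,
          "tol": c.tol, "passed": c.passed} for c in checks]
    )
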