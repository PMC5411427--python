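"""2^-ddCt relative expression: replicate collapse, fold identities,
shift invariance and monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vvlung.errors import InvalidArgumentError, MissingCalibratorError
from vvlung.gene_expr import (
    REFERENCE_GENE,
    collapse_replicates,
    fold_change_ddct,
    summarize_folds,
)


def make_ct_table(rows):
    return pd.DataFrame(rows, columns=["animal_id", "group", "lung_side", "gene", "replicate", "ct"])


def simple_table(gene_ct_by_animal, ref_ct=18.0, group="IR-VCV", cal_gene_ct=23.0):
    """One target gene; NV calibrator animals at dCt = cal_gene_ct - ref_ct."""
    rows = []
    for aid, ct in gene_ct_by_animal.items():
        for rep in (1, 2, 3):
            rows.append((aid, group, "left", "IL6", rep, ct))
            rows.append((aid, group, "left", REFERENCE_GENE, rep, ref_ct))
    for aid in ("NV1", "NV2"):
        for rep in (1, 2, 3):
            rows.append((aid, "NV-Sham", "left", "IL6", rep, cal_gene_ct))
            rows.append((aid, "NV-Sham", "left", REFERENCE_GENE, rep, ref_ct))
    return make_ct_table(rows)


# ------------------------------------------------------------ replicates


def test_replicate_mean_and_sd():
    t = make_ct_table([("A1", "IR-VCV", "left", "IL6", r, ct)
                       for r, ct in [(1, 20.1), (2, 20.0), (3, 19.9)]])
    out = collapse_replicates(t)
    assert out["ct_mean"].iloc[0] == pytest.approx(20.0)
    assert out["ct_sd"].iloc[0] == pytest.approx(0.1)
    assert not out["qc_flag"].iloc[0]


def test_single_replicate_tolerated_but_flagged():
    t = make_ct_table([("A1", "IR-VCV", "left", "IL6", 1, 22.5)])
    out = collapse_replicates(t)
    assert out["ct_mean"].iloc[0] == 22.5
    assert out["ct_sd"].iloc[0] == 0.0
    assert out["qc_flag"].iloc[0]


def test_high_replicate_sd_flagged():
    t = make_ct_table([("A1", "IR-VCV", "left", "IL6", r, ct)
                       for r, ct in [(1, 20.0), (2, 21.5), (3, 20.2)]])
    assert collapse_replicates(t)["qc_flag"].iloc[0]


def test_nonpositive_ct_rejected():
    t = make_ct_table([("A1", "IR-VCV", "left", "IL6", 1, -1.0)])
    with pytest.raises(InvalidArgumentError):
        collapse_replicates(t)


# ------------------------------------------------------------ fold changes


def test_fold_one_when_dct_equals_calibrator():
    t = simple_table({"A1": 23.0})  # dCt 5 == calibrator dCt 5
    folds = fold_change_ddct(collapse_replicates(t))
    a1 = folds[folds.animal_id == "A1"]
    assert a1["fold_change"].iloc[0] == pytest.approx(1.0)


def test_one_cycle_higher_halves_fold():
    t = simple_table({"A1": 24.0})  # one cycle above calibrator
    folds = fold_change_ddct(collapse_replicates(t))
    assert folds[folds.animal_id == "A1"]["fold_change"].iloc[0] == pytest.approx(0.5)


def test_hand_computed_fold():
    # dCt_animal = 3.2, calibrator mean dCt = 5.0 -> fold 2^1.8
    t = simple_table({"A1": 18.0 + 3.2})
    folds = fold_change_ddct(collapse_replicates(t))
    assert folds[folds.animal_id == "A1"]["fold_change"].iloc[0] == pytest.approx(2**1.8)


def test_calibrator_fold_geometric_mean_is_one(rng):
    cts = {f"S{i}": 23.0 + rng.normal(0, 0.7) for i in range(6)}
    rows = []
    for aid, ct in cts.items():
        for rep in (1, 2, 3):
            rows.append((aid, "NV-Sham", "left", "IL6", rep, ct))
            rows.append((aid, "NV-Sham", "left", REFERENCE_GENE, rep, 18.0))
    folds = fold_change_ddct(collapse_replicates(make_ct_table(rows)),
                             calibrator_group="NV-Sham")
    gm = np.exp(np.log(folds["fold_change"]).mean())
    assert gm == pytest.approx(1.0, abs=1e-12)


def test_global_ct_shift_invariance():
    t1 = simple_table({"A1": 21.5})
    t2 = t1.copy()
    t2["ct"] = t2["ct"] + 3.7  # shift every Ct (target and reference alike)
    f1 = fold_change_ddct(collapse_replicates(t1))
    f2 = fold_change_ddct(collapse_replicates(t2))
    assert np.allclose(f1["fold_change"], f2["fold_change"])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(ct=st.floats(19.0, 26.0), delta=st.floats(0.1, 3.0))
def test_fold_strictly_decreasing_in_target_ct(ct, delta):
    f_lo = fold_change_ddct(collapse_replicates(simple_table({"A1": ct})))
    f_hi = fold_change_ddct(collapse_replicates(simple_table({"A1": ct + delta})))
    assert f_hi[f_hi.animal_id == "A1"]["fold_change"].iloc[0] < \
        f_lo[f_lo.animal_id == "A1"]["fold_change"].iloc[0]


def test_side_restricted_calibration():
    """Left and right lungs calibrate against their own NV side."""
    rows = []
    for side, cal_ct in (("left", 23.0), ("right", 21.0)):
        for rep in (1, 2, 3):
            rows.append(("A1", "IR-VCV", side, "IL6", rep, 23.0))
            rows.append(("A1", "IR-VCV", side, REFERENCE_GENE, rep, 18.0))
            rows.append(("NV1", "NV-Sham", side, "IL6", rep, cal_ct))
            rows.append(("NV1", "NV-Sham", side, REFERENCE_GENE, rep, 18.0))
    folds = fold_change_ddct(collapse_replicates(make_ct_table(rows)))
    a1 = folds[folds.animal_id == "A1"].set_index("lung_side")
    assert a1.loc["left", "fold_change"] == pytest.approx(1.0)
    assert a1.loc["right", "fold_change"] == pytest.approx(0.25)  # 2 cycles above calibrator


def test_missing_calibrator_side_raises():
    rows = []
    for rep in (1, 2, 3):
        rows.append(("A1", "IR-VCV", "right", "IL6", rep, 23.0))
        rows.append(("A1", "IR-VCV", "right", REFERENCE_GENE, rep, 18.0))
        rows.append(("NV1", "NV-Sham", "left", "IL6", rep, 23.0))
        rows.append(("NV1", "NV-Sham", "left", REFERENCE_GENE, rep, 18.0))
    with pytest.raises(MissingCalibratorError):
        fold_change_ddct(collapse_replicates(make_ct_table(rows)))


def test_missing_reference_gene_raises():
    t = make_ct_table([("A1", "IR-VCV", "left", "IL6", 1, 20.0)])
    with pytest.raises(InvalidArgumentError):
        fold_change_ddct(collapse_replicates(t))


def test_summarize_folds_median_iqr():
    t = simple_table({f"A{i}": ct for i, ct in enumerate([21.0, 22.0, 23.0, 24.0])})
    folds = fold_change_ddct(collapse_replicates(t))
    summ = summarize_folds(folds)
    row = summ[(summ.group == "IR-VCV") & (summ.gene == "IL6")].iloc[0]
    assert row["n"] == 4
    assert row["q1"] <= row["median"] <= row["q3"]
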