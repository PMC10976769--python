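import itertools

import numpy as np
import pandas as pd
import pytest

from mirfam import expression as ex
from mirfam.synthdata import SimSpec, gen_ct_table


def tiny_ct_table():
    """One gene + references in two tissues, 2 timepoints, 3 bio reps."""
    rows = []
    for tissue, ref in (("root", "EF-1a"), ("leaf", "18S")):
        for tp in (0.0, 6.0):
            for bio in (1, 2, 3):
                rows.append(dict(tissue=tissue, treatment="PEG", timepoint_h=tp,
                                 gene_id=ref, gene_class="reference",
                                 bio_rep=bio, tech_rep=1, ct=20.0))
                # gene 4-fold induced at 6 h (log2fc 2 => Ct down 2)
                ct = 25.0 - (2.0 if tp == 6.0 else 0.0)
                rows.append(dict(tissue=tissue, treatment="PEG", timepoint_h=tp,
                                 gene_id="HB15", gene_class="target",
                                 bio_rep=bio, tech_rep=1, ct=ct))
    return pd.DataFrame(rows)


class TestNormalize:
    def test_delta_ct_is_target_minus_reference(self):
        d = ex.normalize(tiny_ct_table())
        at0 = d[(d.timepoint_h == 0.0) & (d.tissue == "root")]
        assert set(at0.delta_ct) == {5.0}

    def test_technical_replicates_averaged_first(self):
        rows = []
        for tech, ct in ((1, 24.9), (2, 25.0), (3, 25.1)):
            rows.append(dict(tissue="root", treatment="PEG", timepoint_h=0.0,
                             gene_id="g", gene_class="target", bio_rep=1,
                             tech_rep=tech, ct=ct))
        rows.append(dict(tissue="root", treatment="PEG", timepoint_h=0.0,
                         gene_id="EF-1a", gene_class="reference", bio_rep=1,
                         tech_rep=1, ct=20.0))
        d = ex.normalize(pd.DataFrame(rows))
        assert d.delta_ct.iloc[0] == pytest.approx(5.0)

    def test_tissue_specific_reference_genes(self):
        table = tiny_ct_table()
        # corrupt the leaf reference: shift 18S by 1 cycle; only leaf
        # delta_ct should move
        table.loc[(table.gene_id == "18S"), "ct"] += 1.0
        d = ex.normalize(table)
        root0 = d[(d.tissue == "root") & (d.timepoint_h == 0.0)].delta_ct.iloc[0]
        leaf0 = d[(d.tissue == "leaf") & (d.timepoint_h == 0.0)].delta_ct.iloc[0]
        assert root0 == pytest.approx(5.0)
        assert leaf0 == pytest.approx(4.0)

    def test_missing_reference_is_an_error_naming_the_sample(self):
        table = tiny_ct_table()
        table = table[~((table.gene_id == "EF-1a") & (table.bio_rep == 2)
                        & (table.timepoint_h == 6.0))]
        with pytest.raises(ValueError, match="bio_rep 2"):
            ex.normalize(table)


class TestDeltaDeltaCt:
    def test_calibrator_has_rq_exactly_one(self):
        d = ex.normalize(tiny_ct_table())
        results = ex.delta_delta_ct(d)
        for r in results:
            if r.timepoint_h == 0.0:
                assert r.rq == 1.0
                assert r.log2fc == 0.0

    def test_one_cycle_drop_doubles_relative_quantity(self):
        d = ex.normalize(tiny_ct_table())
        d.loc[d.timepoint_h == 6.0, "delta_ct"] = 4.0  # ddCt = -1
        results = ex.delta_delta_ct(d)
        for r in results:
            if r.timepoint_h == 6.0:
                assert r.rq == pytest.approx(2.0)
                assert r.log2fc == pytest.approx(1.0)

    def test_log2fc_matches_log2_of_rq(self):
        d = ex.normalize(tiny_ct_table())
        for r in ex.delta_delta_ct(d):
            assert r.log2fc == pytest.approx(np.log2(r.rq), abs=1e-12)

    def test_antisymmetric_under_calibrator_swap(self):
        d = ex.normalize(tiny_ct_table())
        fwd = {(r.tissue, r.timepoint_h): r.log2fc
               for r in ex.delta_delta_ct(d, calibrator_timepoint=0.0)}
        rev = {(r.tissue, r.timepoint_h): r.log2fc
               for r in ex.delta_delta_ct(d, calibrator_timepoint=6.0)}
        for tissue in ("root", "leaf"):
            assert fwd[(tissue, 6.0)] == pytest.approx(-rev[(tissue, 0.0)])

    def test_missing_calibrator_is_an_error(self):
        d = ex.normalize(tiny_ct_table())
        with pytest.raises(ValueError, match="calibrator"):
            ex.delta_delta_ct(d[d.timepoint_h != 0.0])

    def test_planted_fold_change_recovered_within_error_bound(self):
        # the estimate's sd is sigma*sqrt(2/n_tech)*sqrt(2/n_bio) (both
        # the sample and the calibrator mean are noisy); the mean
        # absolute error over all conditions must sit well inside
        # 3*sigma*sqrt(2/n_reps)
        spec = SimSpec(seed=13, planted_log2fc=2.0, ct_noise_sd=0.1)
        cts, _ = gen_ct_table(spec)
        d = ex.normalize(cts)
        results = ex.delta_delta_ct(d)
        errors = [abs(r.log2fc - 2.0) for r in results if r.timepoint_h != 0.0]
        assert np.mean(errors) < 3.0 * 0.1 * np.sqrt(2.0 / 3.0)
        assert np.mean([r.log2fc for r in results if r.timepoint_h != 0.0]) == \
            pytest.approx(2.0, abs=0.05)


class TestSignificanceLetters:
    def _frame(self, groups: dict) -> pd.DataFrame:
        rows = []
        for tp, values in groups.items():
            for bio, v in enumerate(values, start=1):
                rows.append(dict(tissue="root", treatment="PEG", timepoint_h=tp,
                                 gene_id="g", bio_rep=bio, delta_ct=v))
        return pd.DataFrame(rows)

    def test_identical_groups_share_a_letter(self):
        d = self._frame({0.0: [5.0, 5.01, 4.99], 6.0: [5.0, 5.01, 4.99],
                         12.0: [5.0, 4.99, 5.01]})
        letters = ex.significance_letters(d, "g", "root", "PEG")
        assert set(letters.values()) == {"a"}

    def test_widely_separated_groups_get_distinct_letters(self):
        d = self._frame({0.0: [5.0, 5.01, 4.99], 6.0: [1.0, 1.01, 0.99]})
        letters = ex.significance_letters(d, "g", "root", "PEG")
        assert letters[6.0] == "a"  # lower dCt = higher expression
        assert letters[0.0] == "b"

    def test_letter_partition_consistent_with_all_pairs_tests(self):
        # four groups: two close pairs far apart
        d = self._frame({
            0.0: [10.0, 10.05, 9.95],
            6.0: [10.1, 10.0, 10.05],
            12.0: [2.0, 2.05, 1.95],
            24.0: [2.1, 2.0, 2.05],
        })
        letters = ex.significance_letters(d, "g", "root", "PEG")
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = d.delta_ct.to_numpy()
        labels = d.timepoint_h.astype(str).to_numpy()
        res = pairwise_tukeyhsd(values, labels, alpha=0.05)
        table = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        for row in table.itertuples(index=False):
            a, b = float(row.group1), float(row.group2)
            share = bool(set(letters[a]) & set(letters[b]))
            assert share == (not row.reject)

    def test_single_replicate_group_withholds_letters(self, caplog):
        d = self._frame({0.0: [5.0], 6.0: [1.0, 1.1]})
        with caplog.at_level("WARNING", logger="mirfam"):
            letters = ex.significance_letters(d, "g", "root", "PEG")
        assert set(letters.values()) == {""}

    def test_fewer_than_two_conditions_rejected(self):
        d = self._frame({0.0: [5.0, 5.1]})
        with pytest.raises(ValueError, match="2 conditions"):
            ex.significance_letters(d, "g", "root", "PEG")
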