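"""Junction features: hydrophobicity, V/N/J decomposition, KS comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers_oracles import ks_exact_oracle
from pitmatch import (
    EISENBERG,
    compare_feature_distributions,
    decompose_junction,
    hydrophobicity,
    parse_imgt_feature_table,
    specificity_grouping,
)

NT = "ACGT"
nt_strings = st.text(alphabet=NT, min_size=0, max_size=45)


class TestHydrophobicity:
    def test_scale_anchor_values(self):
        assert hydrophobicity("P") == 0.12
        assert hydrophobicity("Y") == 0.26

    def test_mean_of_two_residues(self):
        assert hydrophobicity("PY") == pytest.approx((0.12 + 0.26) / 2)

    @pytest.mark.parametrize("aa", sorted(EISENBERG))
    def test_homopolymer_equals_table_value(self, aa):
        assert hydrophobicity(aa * 7) == pytest.approx(EISENBERG[aa])

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'X'"):
            hydrophobicity("CAXF")

    def test_range_is_bounded_by_scale(self, rng):
        letters = sorted(EISENBERG)
        for _ in range(100):
            s = "".join(rng.choice(letters, size=rng.integers(1, 20)))
            v = hydrophobicity(s)
            assert -2.53 <= v <= 1.38

    def test_sum_and_anchor_exclusion_options(self):
        assert hydrophobicity("PY", aggregate="sum") == pytest.approx(0.38)
        assert hydrophobicity("CPF", include_anchors=False) == pytest.approx(0.12)


class TestDecomposition:
    def test_constructed_junction_recovered(self):
        v, j = "TGTGCTGTG", "AACACCTTC"
        junction = v + "CCG" + j
        assert decompose_junction(junction, v, j) == (9, 3, 9)

    def test_zero_insertion(self):
        v, j = "TGTGCT", "AACTTC"
        assert decompose_junction(v + j, v, j) == (6, 0, 6)

    def test_overlap_resolved_v_first(self):
        # junction fully matched by V prefix and J suffix simultaneously
        v = "AAAA"
        j = "AAAA"
        junction = "AAAA"
        v3, n, j5 = decompose_junction(junction, v, j)
        assert (v3, n, j5) == (4, 0, 0)  # V claim maximized first

    def test_exhaustive_small_case_oracle(self):
        # enumerate all junctions of length <= 4 over {A, C} against short germlines
        v, j = "AC", "CA"
        from itertools import product

        for L in range(5):
            for tup in product("AC", repeat=L):
                junction = "".join(tup)
                v3, n, j5 = decompose_junction(junction, v, j)
                # oracle: maximize v3 first, then j5, exact prefix/suffix matches
                best_v3 = 0
                for i in range(min(L, len(v)), 0, -1):
                    if junction[:i] == v[:i]:
                        best_v3 = i
                        break
                best_j5 = 0
                for i in range(min(L - best_v3, len(j)), 0, -1):
                    if junction[-i:] == j[-i:]:
                        best_j5 = i
                        break
                assert (v3, n, j5) == (best_v3, L - best_v3 - best_j5, best_j5)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(nt_strings, nt_strings, nt_strings)
    def test_length_conservation(self, junction, v, j):
        v3, n, j5 = decompose_junction(junction, v, j)
        assert v3 + n + j5 == len(junction)
        assert min(v3, n, j5) >= 0

    def test_conservation_on_simulated_junctions(self, germline, small_simulation):
        cells, truth = small_simulation
        for row in truth.itertuples(index=False):
            if row.v3_nt is None or np.isnan(row.v3_nt):
                continue
            v = germline.v_segments[row.locus][row.v_gene]
            j = germline.j_segments[row.locus][row.j_gene]
            v3, n, j5 = decompose_junction(row.junction_nt, v, j)
            assert v3 + n + j5 == len(row.junction_nt)
            # recovered germline total can only exceed the planted one
            # (N nucleotides occasionally extend a germline match by chance)
            assert v3 >= row.v3_nt
            assert v3 + j5 >= row.v3_nt + row.j5_nt


class TestIMGTTable:
    def _write(self, tmp_path, rows):
        df = pd.DataFrame(rows)
        path = tmp_path / "imgt.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_region_lengths_roundtrip(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                {
                    "JUNCTION (AA)": "CAVRMNTGFQKLVF",
                    "locus": "TRA",
                    "JUNCTION": "",
                    "CDR1-IMGT length": 18,
                    "CDR2-IMGT length": 24,
                    "CDR3-IMGT length": 36,
                    "FR1-IMGT length": 75,
                    "N-REGION length": 4,
                }
            ],
        )
        (row,) = parse_imgt_feature_table(path)
        assert row.cdr1_nt == 18 and row.n_region_nt == 4
        assert row.junction_length_nt == 36 + 6  # junction = CDR3 + anchors
        assert row.junction_length_aa == 14

    def test_junction_nt_length_used_when_present(self, tmp_path):
        path = self._write(
            tmp_path,
            [{"JUNCTION (AA)": "CASSF", "JUNCTION": "TGT" * 5, "CDR3-IMGT length": 9}],
        )
        (row,) = parse_imgt_feature_table(path)
        assert row.junction_length_nt == 15

    def test_missing_cdr3_column_errors(self, tmp_path):
        path = self._write(tmp_path, [{"JUNCTION (AA)": "CASSF"}])
        with pytest.raises(ValueError, match="CDR3"):
            parse_imgt_feature_table(path)


class TestKSComparisons:
    def test_identical_samples(self):
        df = pd.DataFrame({"junction_aa": [f"j{i}" for i in range(8)],
                           "length": [1, 2, 3, 4, 1, 2, 3, 4]})
        labels = {f"j{i}": i < 4 for i in range(8)}
        out = compare_feature_distributions(df, labels, ["length"])
        assert out.loc[0, "ks_D"] == 0.0 and out.loc[0, "p"] == 1.0

    def test_exact_small_sample_enumeration(self, rng):
        for _ in range(12):
            n, m = int(rng.integers(3, 9)), int(rng.integers(3, 9))
            a = rng.normal(0, 1, size=n)
            b = rng.normal(0.5, 1, size=m)
            d_oracle, p_oracle = ks_exact_oracle(a, b)
            df = pd.DataFrame(
                {
                    "junction_aa": [f"x{i}" for i in range(n + m)],
                    "f": np.concatenate([a, b]),
                }
            )
            labels = {f"x{i}": i < n for i in range(n + m)}
            out = compare_feature_distributions(df, labels, ["f"])
            assert out.loc[0, "ks_D"] == pytest.approx(d_oracle, rel=1e-9)
            assert out.loc[0, "p"] == pytest.approx(p_oracle, rel=1e-9)

    def test_shift_detected_with_median_gap(self, rng):
        n = 500
        a = rng.normal(39, 3, size=n)
        b = rng.normal(42, 3, size=n)
        df = pd.DataFrame(
            {"junction_aa": [f"x{i}" for i in range(2 * n)], "len_nt": np.concatenate([a, b])}
        )
        labels = {f"x{i}": i < n for i in range(2 * n)}
        out = compare_feature_distributions(df, labels, ["len_nt"])
        assert out.loc[0, "p"] < 1e-4
        assert out.loc[0, "median_false"] - out.loc[0, "median_true"] == pytest.approx(3, abs=1)

    def test_empty_group_errors(self):
        df = pd.DataFrame({"junction_aa": ["a", "b"], "f": [1.0, 2.0]})
        with pytest.raises(ValueError, match="observations"):
            compare_feature_distributions(df, {"a": True, "b": True}, ["f"])


class TestSpecificityGrouping:
    def _vdjdb(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "v.segm", "j.segm", "cdr3", "antigen.epitope"]
        )

    def test_multi_vs_single_labels(self):
        df = self._vdjdb(
            [
                ("TRA", "TRAV1*01", "TRAJ4", "CAVRF", "EPITOPE1"),
                ("TRA", "TRAV1", "TRAJ4", "CAVRF", "EPITOPE2"),
                ("TRA", "TRAV2", "TRAJ5", "CAWWF", "EPITOPE1"),
                ("TRA", "TRAV2", "TRAJ5", "CAWWF", "EPITOPE1"),
                ("TRB", "TRBV9", "TRBJ1", "CASSF", "EPITOPE9"),
            ]
        )
        out = specificity_grouping(df, locus="TRA")
        assert len(out) == 2
        by_cdr3 = out.set_index("cdr3_aa")
        assert bool(by_cdr3.loc["CAVRF", "multi_specific"])
        assert not bool(by_cdr3.loc["CAWWF", "multi_specific"])

    def test_rows_without_epitope_excluded(self):
        df = self._vdjdb([("TRA", "TRAV1", "TRAJ4", "CAVRF", ""),
                          ("TRA", "TRAV1", "TRAJ4", "CAVRF", "E1")])
        out = specificity_grouping(df, locus="TRA")
        assert out.attrs["excluded_no_epitope"] == 1
        assert not out["multi_specific"].any()

    def test_planted_multi_rate_recovered_exactly(self, rng):
        rows = []
        n = 200
        for i in range(n):
            multi = i < 20  # planted 10%
            rows.append(("TRA", f"TRAV{i % 8}", f"TRAJ{i % 5}", f"CA{i:03d}F", "E1"))
            if multi:
                rows.append(("TRA", f"TRAV{i % 8}", f"TRAJ{i % 5}", f"CA{i:03d}F", "E2"))
        out = specificity_grouping(self._vdjdb(rows), locus="TRA")
        assert out["multi_specific"].mean() == pytest.approx(0.10)
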