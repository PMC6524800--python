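"""Dataset curation: parsing, trimming, filtering, identity clustering."""

import numpy as np
import pytest

from corecluster import (
    FilterConfig,
    filter_dataset,
    identity_cluster,
    pairwise_identity,
    read_structure,
    trim_to_range,
    write_structure,
)
from corecluster.structure_io import ParseError, ResidueRecord, StructureModel

from conftest import make_trace_model


def _model(model_id, n, resolution=None, n_missing=0, spacing=4.5):
    # spacing > 4 keeps ResidueRecord construction trivial and valid
    residues = [
        ResidueRecord("A", i + 1, "", "A", (spacing * i, 0.0, 0.0))
        for i in range(n)
    ]
    return StructureModel(model_id, residues, resolution=resolution, n_missing=n_missing)


class TestReadWrite:
    def test_round_trip_preserves_coordinates_to_pdb_precision(self, tmp_path):
        m = make_trace_model(30, seed=11, model_id="rt_A")
        path = tmp_path / "rt.pdb"
        write_structure(m, path)
        back = read_structure(path, "A", model_id="rt_A")
        assert back.sequence == m.sequence
        assert np.allclose(back.ca_coords, m.ca_coords, atol=1.5e-3)
        assert [r.res_seq for r in back.residues] == [r.res_seq for r in m.residues]

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  CA ATHR A  10       1.000   0.000   0.000  0.60 10.00           C\n"
            "ATOM      2  CA BTHR A  10       9.000   9.000   9.000  0.40 10.00           C\n"
            "ATOM      3  CA  GLY A  11       4.800   0.000   0.000  1.00 10.00           C\n"
            "ATOM      4  CA  ALA A  12       8.600   0.000   0.000  1.00 10.00           C\n"
            "END\n"
        )
        p = tmp_path / "altloc.pdb"
        p.write_text(pdb)
        m = read_structure(p, "A")
        assert len(m) == 3
        assert m.residues[0].ca_xyz == (1.0, 0.0, 0.0)

    def test_numbering_gap_counts_missing_residues(self, tmp_path):
        lines = []
        for k, num in enumerate((10, 11, 14, 15)):
            lines.append(
                f"ATOM  {k + 1:>5d}  CA  GLY A{num:>4d}    {4.8 * k:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 10.00           C"
            )
        p = tmp_path / "gap.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        m = read_structure(p, "A")
        assert len(m) == 4
        assert m.n_missing == 2

    def test_seqres_takes_precedence_over_gaps(self, tmp_path):
        # SEQRES declares 6 residues; only 4 have coordinates -> 2 missing
        pdb = (
            "SEQRES   1 A    6  GLY GLY GLY GLY GLY GLY\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "ATOM      2  CA  GLY A   2       4.800   0.000   0.000  1.00 10.00           C\n"
            "ATOM      3  CA  GLY A   3       9.600   0.000   0.000  1.00 10.00           C\n"
            "ATOM      4  CA  GLY A   4      14.400   0.000   0.000  1.00 10.00           C\n"
            "END\n"
        )
        p = tmp_path / "seqres.pdb"
        p.write_text(pdb)
        m = read_structure(p, "A")
        assert m.n_missing == 2

    @pytest.mark.parametrize(
        "case",
        ["missing_file", "bad_chain", "no_ca"],
    )
    def test_parse_errors_name_the_problem(self, tmp_path, case):
        if case == "missing_file":
            with pytest.raises(ParseError, match="not found"):
                read_structure(tmp_path / "absent.pdb", "A")
        elif case == "bad_chain":
            p = tmp_path / "x.pdb"
            write_structure(make_trace_model(10, 1), p)
            with pytest.raises(ParseError, match="chain 'B'"):
                read_structure(p, "B")
        else:
            p = tmp_path / "noca.pdb"
            p.write_text(
                "ATOM      1  CB  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\nEND\n"
            )
            with pytest.raises(ParseError, match="C-alpha"):
                read_structure(p, "A")


class TestTrim:
    def test_plain_range(self):
        m = _model("m", 100)
        t = trim_to_range(m, 20, 40)
        assert len(t) == 21
        assert t.residues[0].res_seq == 20

    def test_insertion_code_shares_base_number(self):
        residues = [
            ResidueRecord("A", 19, "", "A", (0.0, 0.0, 0.0)),
            ResidueRecord("A", 20, "", "A", (5.0, 0.0, 0.0)),
            ResidueRecord("A", 20, "A", "A", (10.0, 0.0, 0.0)),
            ResidueRecord("A", 21, "", "A", (15.0, 0.0, 0.0)),
        ]
        m = StructureModel("ins", residues)
        t = trim_to_range(m, 20, 21)
        assert len(t) == 3

    def test_empty_range_is_an_error(self):
        with pytest.raises(ValueError):
            trim_to_range(_model("m", 100), 200, 300)


class TestFilter:
    def test_toy_table(self):
        models = [
            _model("m1", 140, resolution=2.0, n_missing=0),
            _model("m2", 137, resolution=2.0, n_missing=0),
            _model("m3", 150, resolution=4.5, n_missing=0),
            _model("m4", 139, resolution=3.9, n_missing=12),
            _model("m5", 200, resolution=2.5, n_missing=3),
        ]
        kept, report = filter_dataset(models, FilterConfig())
        assert [m.model_id for m in kept] == ["m1", "m5"]
        failed = dict(zip(report["model_id"], report["failed_rules"]))
        assert failed["m2"] == "min_length"
        assert failed["m3"] == "max_resolution"
        assert failed["m4"] == "max_missing"

    def test_boundary_length_is_inclusive(self):
        kept, _ = filter_dataset([_model("b", 138, resolution=2.0)])
        assert len(kept) == 1

    def test_unknown_resolution_passes(self):
        kept, _ = filter_dataset([_model("nmr", 150, resolution=None)])
        assert len(kept) == 1

    def test_empty_input(self):
        kept, report = filter_dataset([])
        assert kept == [] and len(report) == 0

    def test_idempotent(self):
        models = [
            _model("a", 140, resolution=2.0),
            _model("b", 100, resolution=2.0),
            _model("c", 160, resolution=5.0),
        ]
        kept, _ = filter_dataset(models)
        again, report = filter_dataset(kept)
        assert [m.model_id for m in again] == [m.model_id for m in kept]
        assert report["kept"].all()


class TestIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEFG", "ACDEFG") == 1.0

    def test_no_positive_local_alignment(self):
        # A-vs-W scores negative everywhere under BLOSUM62
        assert pairwise_identity("AAAA", "WWWW") == 0.0

    def test_symmetry_and_self_identity(self):
        rng = np.random.default_rng(3)
        from corecluster.structure_io import STANDARD_AA

        seqs = [
            "".join(STANDARD_AA[i] for i in rng.integers(20, size=40)) for _ in range(4)
        ]
        for s in seqs:
            assert pairwise_identity(s, s) == 1.0
        for s, t in zip(seqs, seqs[1:]):
            assert pairwise_identity(s, t) == pairwise_identity(t, s)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")


class TestIdentityCluster:
    @staticmethod
    def _seq_model(model_id, seq):
        return StructureModel(
            model_id,
            [
                ResidueRecord("A", i + 1, "", c, (4.5 * i, 0.0, 0.0))
                for i, c in enumerate(seq)
            ],
        )

    def test_exact_duplicates_collapse(self):
        a = self._seq_model("a", "ACDEFGHIKL" * 3)
        b = self._seq_model("b", "ACDEFGHIKL" * 3)
        assert len(identity_cluster([a, b], 0.70)) == 1

    def test_dissimilar_sequences_stay(self):
        rng = np.random.default_rng(9)
        from corecluster.structure_io import STANDARD_AA

        models = [
            self._seq_model(f"m{k}", "".join(STANDARD_AA[i] for i in rng.integers(20, size=50)))
            for k in range(3)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert pairwise_identity(models[i].sequence, models[j].sequence) < 0.70
        assert len(identity_cluster(models, 0.70)) == 3

    def test_greedy_chain_rule(self):
        # A~B above threshold, A~C below: B joins A's cluster, C founds its own
        rng = np.random.default_rng(5)
        from corecluster.structure_io import STANDARD_AA

        base = "".join(STANDARD_AA[i] for i in rng.integers(20, size=100))
        b_seq = list(base[:95])
        for pos in rng.choice(95, size=8, replace=False):
            b_seq[pos] = STANDARD_AA[(STANDARD_AA.index(b_seq[pos]) + 1) % 20]
        c_seq = list(base[:90])
        for pos in rng.choice(90, size=45, replace=False):
            c_seq[pos] = STANDARD_AA[(STANDARD_AA.index(c_seq[pos]) + 7) % 20]
        a = self._seq_model("a", base)
        b = self._seq_model("b", "".join(b_seq))
        c = self._seq_model("c", "".join(c_seq))
        assert pairwise_identity(a.sequence, b.sequence) > 0.70
        assert pairwise_identity(a.sequence, c.sequence) <= 0.70
        reps = identity_cluster([a, b, c], 0.70)
        assert sorted(m.model_id for m in reps) == ["a", "c"]

    def test_max_identity_one_keeps_all_distinct(self):
        a = self._seq_model("a", "ACDEFGHIKL")
        b = self._seq_model("b", "ACDEFGHIKL")
        c = self._seq_model("c", "ACDEFGHIKM")
        reps = identity_cluster([a, b, c], 1.0)
        assert sorted(m.model_id for m in reps) == ["a", "c"]
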