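"""Layout / quantification / profile IO and the reaction-filename grammar."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinarray.array_model import (
    ArrayLayout,
    LayoutError,
    PeptideAnnotation,
    QuantificationError,
    StudyDesign,
    default_layout,
    parse_reaction_filename,
    reaction_filename,
    read_layout,
    read_profile,
    read_quantification,
    write_layout,
    write_profile,
    write_quantification,
)
from kinarray.scoring import KinomeProfile

from conftest import make_layout, make_quant


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class TestLayout:
    def test_basic_parse_preserves_order_and_categories(self, tmp_path):
        p = tmp_path / "layout.tsv"
        write_lines(p, [
            "peptide_id\tblock\trow\tcol\tcategories",
            "p1\t0\t0\t0\tPAK;mTOR",
            "p2\t0\t0\t1\t",
            "p3\t0\t1\t0\tAMPK",
            "p4\t0\t1\t1\tPAK",
        ])
        layout = read_layout(p)
        assert layout.n_peptides == 4
        assert layout.peptide_ids == ("p1", "p2", "p3", "p4")
        assert layout.categories == {"PAK", "mTOR", "AMPK"}
        assert layout.peptides[0].categories == ("PAK", "mTOR")
        assert layout.peptides[1].categories == ()
        assert layout.members("PAK") == ("p1", "p4")

    def test_duplicate_peptide_id_names_offender(self, tmp_path):
        p = tmp_path / "layout.tsv"
        write_lines(p, [
            "peptide_id\tblock\trow\tcol\tcategories",
            "p1\t0\t0\t0\t",
            "p1\t0\t0\t1\t",
        ])
        with pytest.raises(LayoutError, match="p1"):
            read_layout(p)

    def test_missing_column_names_column(self, tmp_path):
        p = tmp_path / "layout.tsv"
        write_lines(p, ["peptide_id\tblock\trow\tcategories", "p1\t0\t0\t"])
        with pytest.raises(LayoutError, match="col"):
            read_layout(p)

    def test_duplicate_grid_position_rejected(self):
        with pytest.raises(LayoutError, match="grid"):
            ArrayLayout(peptides=(
                PeptideAnnotation("a", (0, 0, 0)),
                PeptideAnnotation("b", (0, 0, 0)),
            ))

    def test_layout_roundtrip(self, tmp_path):
        layout = make_layout(6, {"p1": ("PAK",), "p5": ("Chk1/Chk2", "mTOR")},
                             seq=True)
        p = tmp_path / "layout.tsv"
        write_layout(p, layout)
        assert read_layout(p) == layout

    def test_default_shipped_layout_has_1024_peptides(self):
        layout = default_layout()
        assert layout.n_peptides == 1024
        assert {"mTOR", "p70S6K", "AMPK", "Chk1/Chk2", "PAK"} <= layout.categories


class TestReactionFilenameGrammar:
    @staticmethod
    def walk_parse(name):
        """Independent regex-free character-walk parser of the grammar."""
        suffix = ".tsv"
        if len(name) <= len(suffix) or name[-len(suffix):] != suffix:
            return None
        stem = name[: -len(suffix)]
        i = len(stem) - 1
        digits_t = ""
        while i >= 0 and stem[i].isdigit():
            digits_t = stem[i] + digits_t
            i -= 1
        if not digits_t or i < 1 or stem[i] != "t" or stem[i - 1] != "_":
            return None
        i -= 2
        digits_b = ""
        while i >= 0 and stem[i].isdigit():
            digits_b = stem[i] + digits_b
            i -= 1
        if not digits_b or i < 1 or stem[i] != "b" or stem[i - 1] != "_":
            return None
        condition = stem[: i - 1]
        if not condition or int(digits_b) < 1 or int(digits_t) < 1:
            return None
        return condition, int(digits_b), int(digits_t)

    @pytest.mark.parametrize("condition", ["KO", "WT", "Tsc2_null", "ko-2"])
    def test_exhaustive_against_walk_oracle(self, condition):
        for k in range(1, 10):
            for m in range(1, 10):
                name = f"{condition}_b{k}_t{m}.tsv"
                assert self.walk_parse(name) == (condition, k, m)
                assert parse_reaction_filename(name) == (condition, k, m)

    def test_example_from_convention(self):
        assert parse_reaction_filename("KO_b2_t3.tsv") == ("KO", 2, 3)
        assert parse_reaction_filename("/some/dir/KO_b2_t3.tsv") == ("KO", 2, 3)

    @pytest.mark.parametrize("bad", [
        "KO_b2_t3.txt", "KO_b2.tsv", "b2_t3.tsv", "KO_bx_t3.tsv",
        "KO_b2_tx.tsv", "KO_b0_t3.tsv", "KO_b2_t0.tsv", "_b1_t1.tsv",
    ])
    def test_malformed_names_rejected_by_both_parsers(self, bad):
        assert self.walk_parse(bad) is None
        with pytest.raises(QuantificationError):
            parse_reaction_filename(bad)

    def test_roundtrip_with_writer(self):
        assert reaction_filename("KO", 2, 3) == "KO_b2_t3.tsv"


class TestQuantification:
    def test_zero_densities_are_valid(self, tmp_path):
        layout = make_layout(4)
        p = tmp_path / "WT_b1_t1.tsv"
        write_lines(p, ["peptide_id\tforeground_density\tbackground_density"]
                    + [f"p{i}\t0\t0" for i in range(1, 5)])
        q = read_quantification(p, layout)
        assert q.key == ("WT", 1, 1)
        assert np.all(q.foreground == 0) and np.all(q.ok)

    def test_missing_layout_peptide_is_named(self, tmp_path):
        layout = make_layout(4)
        p = tmp_path / "WT_b1_t1.tsv"
        write_lines(p, ["peptide_id\tforeground_density\tbackground_density"]
                    + [f"p{i}\t1\t0" for i in (1, 2, 4)])
        with pytest.raises(QuantificationError, match="p3"):
            read_quantification(p, layout)

    def test_unknown_peptide_and_negative_density_rejected(self, tmp_path):
        layout = make_layout(2)
        p = tmp_path / "WT_b1_t1.tsv"
        write_lines(p, ["peptide_id\tforeground_density\tbackground_density",
                        "p1\t1\t0", "p2\t1\t0", "px\t1\t0"])
        with pytest.raises(QuantificationError, match="px"):
            read_quantification(p, layout)
        write_lines(p, ["peptide_id\tforeground_density\tbackground_density",
                        "p1\t-1\t0", "p2\t1\t0"])
        with pytest.raises(QuantificationError, match="negative"):
            read_quantification(p, layout)

    def test_explicit_metadata_wins_over_filename(self, tmp_path):
        layout = make_layout(2)
        p = tmp_path / "WT_b1_t1.tsv"
        write_lines(p, ["peptide_id\tforeground_density\tbackground_density",
                        "p1\t1\t0", "p2\t1\t0"])
        q = read_quantification(p, layout, condition="KO", bio_rep=2, tech_rep=3)
        assert q.key == ("KO", 2, 3)

    def test_spot_density_alias_and_flag_column(self, tmp_path):
        layout = make_layout(2)
        p = tmp_path / "WT_b1_t1.tsv"
        write_lines(p, ["peptide_id\tspot_density\tbackground_density\tflag",
                        "p1\t5\t1\tok", "p2\t6\t1\tbad_spot"])
        q = read_quantification(p, layout)
        assert list(q.foreground) == [5.0, 6.0]
        assert list(q.ok) == [True, False]

    def test_roundtrip_identity_on_all_fields(self, tmp_path):
        rng = np.random.default_rng(42)
        layout = make_layout(30)
        q = make_quant(
            layout,
            np.exp(rng.normal(6, 1, 30)),
            np.exp(rng.normal(4, 0.3, 30)),
            ok=rng.random(30) > 0.1,
            condition="KO", bio_rep=2, tech_rep=1,
        )
        p = tmp_path / "KO_b2_t1.tsv"
        write_quantification(p, q)
        back = read_quantification(p, layout)
        assert back.key == q.key
        assert np.array_equal(back.foreground, q.foreground)
        assert np.array_equal(back.background, q.background)
        assert np.array_equal(back.ok, q.ok)

    def test_file_row_order_is_irrelevant(self, tmp_path):
        rng = np.random.default_rng(0)
        layout = make_layout(10)
        rows = [f"p{i + 1}\t{rng.integers(1, 100)}\t{rng.integers(0, 10)}"
                for i in range(10)]
        a, b = tmp_path / "WT_b1_t1.tsv", tmp_path / "WT_b1_t2.tsv"
        write_lines(a, ["peptide_id\tforeground_density\tbackground_density"] + rows)
        write_lines(b, ["peptide_id\tforeground_density\tbackground_density"]
                    + rows[::-1])
        qa, qb = read_quantification(a, layout), read_quantification(b, layout)
        assert np.array_equal(qa.foreground, qb.foreground)
        assert np.array_equal(qa.background, qb.background)


class TestProfileIO:
    def test_roundtrip_example(self, tmp_path):
        layout = make_layout(2)
        profile = KinomeProfile(
            condition="KO", R=6, peptide_ids=layout.peptide_ids,
            markov=np.array([6, 0]), n_called=np.array([6, 6]),
        )
        p = tmp_path / "profile.tsv"
        write_profile(p, profile)
        back = read_profile(p)
        assert back == profile
        assert len(p.read_text().splitlines()) == 3  # header + 2 data rows

    def test_empty_profile_writes_header_only(self, tmp_path):
        profile = KinomeProfile(condition="KO", R=6, peptide_ids=(),
                                markov=np.array([], dtype=int),
                                n_called=np.array([], dtype=int))
        p = tmp_path / "profile.tsv"
        write_profile(p, profile)
        assert p.read_text().splitlines() == [
            "peptide_id\tmarkov_score\tn_called\tR\tcondition"
        ]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.data())
    def test_random_profiles_roundtrip_within_bounds(self, tmp_path_factory, data):
        n = data.draw(st.integers(1, 20))
        R = data.draw(st.integers(1, 8))
        n_called = np.array(data.draw(
            st.lists(st.integers(0, R), min_size=n, max_size=n)))
        markov = np.array([data.draw(st.integers(0, int(c))) for c in n_called])
        profile = KinomeProfile(
            condition="WT", R=R,
            peptide_ids=tuple(f"p{i}" for i in range(n)),
            markov=markov, n_called=n_called,
        )
        p = tmp_path_factory.mktemp("prof") / "profile.tsv"
        write_profile(p, profile)
        back = read_profile(p)
        assert back == profile
        assert np.all((back.markov >= 0) & (back.markov <= back.R))

    def test_profile_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            KinomeProfile(condition="WT", R=6, peptide_ids=("p1",),
                          markov=np.array([7]), n_called=np.array([6]))
        with pytest.raises(ValueError):
            KinomeProfile(condition="WT", R=6, peptide_ids=("p1",),
                          markov=np.array([2]), n_called=np.array([1]))


def test_design_reaction_count():
    d = StudyDesign()
    assert d.R == 6 and len(d.reactions()) == 6
    with pytest.raises(ValueError):
        StudyDesign(conditions=("WT", "WT"))
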