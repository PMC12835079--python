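"""Peptide mass arithmetic, HYP ladders, spectral library matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteomsi import (
    CandidateFeature,
    PeptideEntry,
    SpectralLibrary,
    hyp_series,
    match_features,
    peptide_mz,
    relative_mass_error,
)
from osteomsi.annotation import (
    MOD_DELTA,
    PROTON,
    RESIDUE_MASS,
    WATER,
    library_discrepancy_report,
    read_library_tsv,
    recalibrate,
    write_library_tsv,
)


# literature-reported singly protonated monoisotopic masses for
# collagen-domain peptides and the GluFib standard
LITERATURE_MH = [
    ("EGVNDNEEGFFSAR", 0, 1570.6768),     # GluFib spike-in standard
    ("GPAGARGNDGATGAA", 0, 1242.58),      # COL1A1 bone marker
    ("GPQGLAGQR", 0, 883.48),             # COL2A1 cartilage marker
    ("IAGQRGVVGLP", 0, 1066.64),          # COL1A1, unmodified
    ("IAGQRGVVGLP", 1, 1082.63),          # COL1A1 + 1 HYP
    ("GKPGEQGVPGDLGAP", 3, 1426.68),      # COL1A1 + 3 HYP
    ("GLPGERGRPGAP", 3, 1211.61),         # COL1A1 + 3 HYP
]


@pytest.mark.parametrize("seq,n_hyp,printed", LITERATURE_MH)
def test_peptide_mz_matches_literature_values(seq, n_hyp, printed):
    mh = peptide_mz(seq) + n_hyp * MOD_DELTA["HYP"]
    assert mh == pytest.approx(printed, abs=0.01)


def test_single_glycine_closed_form():
    assert peptide_mz("G") == pytest.approx(57.02146 + WATER + PROTON, abs=1e-9)
    assert peptide_mz("G") == pytest.approx(76.0393, abs=1e-4)


def test_peptide_mz_cross_checked_against_pyteomics():
    """Independent oracle: pyteomics monoisotopic [M+H]+ on random peptides."""
    mass = pytest.importorskip("pyteomics.mass")
    rng = np.random.default_rng(8)
    residues = list(RESIDUE_MASS)
    for _ in range(50):
        seq = "".join(rng.choice(residues, size=int(rng.integers(2, 25))))
        ref = mass.calculate_mass(sequence=seq, ion_type="M", charge=1)
        assert peptide_mz(seq) == pytest.approx(ref, abs=5e-4)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_hyp_additivity_and_concatenation(seed):
    rng = np.random.default_rng(seed)
    residues = list(RESIDUE_MASS)
    a = "".join(rng.choice(residues, size=int(rng.integers(1, 15))))
    b = "".join(rng.choice(residues, size=int(rng.integers(1, 15))))
    # peptide-bond identity: concat loses one water, keeps one proton
    lhs = peptide_mz(a + b)
    rhs = peptide_mz(a) + peptide_mz(b) - WATER - PROTON
    assert lhs == pytest.approx(rhs, abs=1e-9)
    # unlocalized HYP additivity is exact
    k = int(rng.integers(1, 4))
    mods = [("unlocalized", "HYP")] * k
    assert peptide_mz(a, mods) - peptide_mz(a) == pytest.approx(
        k * MOD_DELTA["HYP"], abs=1e-12
    )


def test_mod_site_validation():
    with pytest.raises(ValueError, match="allowed"):
        peptide_mz("GAG", [(1, "HYP")])        # HYP must sit on P
    with pytest.raises(ValueError, match="allowed"):
        peptide_mz("GAG", [(2, "deamidation")])  # deamidation needs N/Q
    with pytest.raises(ValueError, match="unknown residue"):
        peptide_mz("GXZ")
    with pytest.raises(ValueError, match="unknown modification"):
        peptide_mz("GPG", [(2, "phospho")])
    # valid placements
    assert peptide_mz("GPG", [(2, "HYP")]) > peptide_mz("GPG")
    assert peptide_mz("GNG", [(2, "deamidation")]) > peptide_mz("GNG")
    assert peptide_mz("MAG", [(1, "oxidationM")]) > peptide_mz("MAG")
    assert peptide_mz("GAG", [(1, "acetylN")]) > peptide_mz("GAG")


# ---------------------------------------------------------------------------
# HYP ladders
# ---------------------------------------------------------------------------

def test_hyp_series_literature_anchors():
    series = dict(hyp_series("GKPGEQGVPGDLGAP"))
    assert series[3] == pytest.approx(1426.68, abs=0.01)
    small = dict(hyp_series("IAGQRGVVGLP"))
    assert small[0] == pytest.approx(1066.64, abs=0.01)
    assert small[1] == pytest.approx(1082.63, abs=0.01)


def test_hyp_series_spacing_exact():
    series = hyp_series("GKPGEQGVPGDLGAP")
    masses = [m for _n, m in series]
    for lo, hi in zip(masses, masses[1:]):
        assert hi - lo == pytest.approx(15.994915, abs=1e-12)
    assert len(series) == 4  # 3 prolines -> 0..3


def test_hyp_series_proline_free_and_clipping():
    assert hyp_series("GAGA") == [(0, pytest.approx(peptide_mz("GAGA")))]
    with pytest.warns(UserWarning, match="clipped"):
        series = hyp_series("GPG", max_hyp=5)
    assert [n for n, _ in series] == [0, 1]


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _cand(mz):
    return CandidateFeature(
        mz=mz, auroc=0.9, direction="up_in_A", n_pixels_A=10, n_pixels_B=10
    )


def _library():
    return SpectralLibrary(
        entries=[
            PeptideEntry("COL1A1", "GPAGARGNDGATGAA"),
            PeptideEntry("COL1A1", "IAGQRGVVGLP", [(11, "HYP")]),
        ]
    )


def test_match_unique_within_2mda():
    theo = peptide_mz("GPAGARGNDGATGAA")
    (ann,) = match_features([_cand(theo + 0.0015)], _library(), tol_da=0.002)
    assert ann.status == "unique"
    entry, delta = ann.matches[0]
    assert entry.sequence == "GPAGARGNDGATGAA"
    assert abs(delta) <= 0.002


def test_match_3mda_off_is_unmatched():
    theo = peptide_mz("GPAGARGNDGATGAA")
    (ann,) = match_features([_cand(theo + 0.003)], _library(), tol_da=0.002)
    assert ann.status == "unmatched"
    assert ann.matches == []


def test_isobaric_entries_reported_ambiguous():
    # L and I are isobaric: two distinct entries, identical mass
    lib = SpectralLibrary(
        entries=[PeptideEntry("A", "GLG"), PeptideEntry("B", "GIG")]
    )
    (ann,) = match_features([_cand(peptide_mz("GLG"))], lib, tol_da=0.002)
    assert ann.status == "ambiguous"
    assert len(ann.matches) == 2


def test_match_tolerance_zero_exact_only():
    theo = peptide_mz("IAGQRGVVGLP", [(11, "HYP")])
    lib = _library()
    (exact,) = match_features([_cand(theo)], lib, tol_da=0.0)
    assert exact.status == "unique"
    (off,) = match_features([_cand(theo + 1e-9)], lib, tol_da=0.0)
    assert off.status == "unmatched"


def test_empty_library_rejected():
    lib = SpectralLibrary(entries=[PeptideEntry("X", "GAG")])
    lib.entries = []
    with pytest.raises(ValueError, match="empty"):
        match_features([_cand(1000.0)], lib, tol_da=0.002)


def test_duplicate_entries_collapsed():
    lib = SpectralLibrary(
        entries=[PeptideEntry("X", "GAG"), PeptideEntry("X", "GAG")]
    )
    assert len(lib) == 1


# ---------------------------------------------------------------------------
# relative mass error and recalibration
# ---------------------------------------------------------------------------

def test_relative_mass_error_arithmetic():
    assert relative_mass_error(1000.0, 1000.0) == 0.0
    assert relative_mass_error(1000.0, 1000.01) == pytest.approx(1e-5, rel=1e-9)


def test_hyp_feature_mass_error_below_literature_bound():
    """The observed m/z 1082.63 sits < 1.5e-5 from the HYP-peptide theory."""
    theo = peptide_mz("IAGQRGVVGLP", [(11, "HYP")])
    assert relative_mass_error(theo, 1082.63) < 1.5e-5


def test_single_point_recalibration():
    out = recalibrate([1000.0, 2000.0], ref_observed=1000.1, ref_theoretical=1000.0)
    np.testing.assert_allclose(out, [999.90001, 1999.80002], rtol=1e-9)


# ---------------------------------------------------------------------------
# library TSV round trip and discrepancy audit
# ---------------------------------------------------------------------------

def test_library_tsv_round_trip(tmp_path):
    lib = SpectralLibrary(
        entries=[
            PeptideEntry("COL1A1", "GKPGEQGVPGDLGAP", [(3, "HYP"), (9, "HYP"), (15, "HYP")]),
            PeptideEntry("COL3A1", "GQRGEPGPQ", [("unlocalized", "HYP")]),
            PeptideEntry("GluFib", "EGVNDNEEGFFSAR"),
        ],
        provenance="test",
    )
    path = tmp_path / "lib.tsv"
    write_library_tsv(lib, path)
    back = read_library_tsv(path)
    assert len(back) == len(lib)
    for a, b in zip(lib.entries, back.entries):
        assert (a.protein, a.sequence, a.mod_key()) == (b.protein, b.sequence, b.mod_key())
        assert a.theoretical_mh == pytest.approx(b.theoretical_mh, abs=1e-6)


def test_inconsistent_stored_mass_rejected():
    with pytest.raises(ValueError, match="recomputed"):
        PeptideEntry("X", "GAG", theoretical_mh=500.0)


def test_discrepancy_report_flags_nominal_16_ladders():
    """Printed ladder values built by subtracting a nominal 16 are flagged."""
    report = library_discrepancy_report(
        {
            "3HYP": ("GKPGEQGVPGDLGAP", 3, 1426.68),
            "1HYP_nominal": ("GKPGEQGVPGDLGAP", 1, 1394.68),
            "0HYP_nominal": ("GKPGEQGVPGDLGAP", 0, 1378.68),
        }
    )
    by_label = report.set_index("label")
    assert not by_label.loc["3HYP", "violates_mass_arithmetic"]
    assert by_label.loc["1HYP_nominal", "violates_mass_arithmetic"]
    assert by_label.loc["0HYP_nominal", "violates_mass_arithmetic"]
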