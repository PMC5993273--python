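import pytest

from equilat import assess_cohort, load_focal_fixture

# Published per-horse reference values: LI, z and p to the printed precision,
# the significance flag, and which test the published p-value actually came
# from ("exact" = doubled binomial tail, "normal" = z approximation — the
# source mixed the two at similar n).  Horse K's printed p (0.717) matches
# neither method (its count-mirrored partner AG prints the exact 0.727) and
# horse E's printed z (1.14) is a digit transposition of 1.41; both are
# flagged "typo" for the affected field.
PRINTED_TABLE = {
    "A": dict(li=42.86, z=2.27, p=0.023, sig="S(R)", p_method="normal"),
    "B": dict(li=55.56, z=2.36, p=0.031, sig="S(R)", p_method="exact"),
    "C": dict(li=-61.91, z=-2.84, p=0.007, sig="S(L)", p_method="exact"),
    "D": dict(li=14.29, z=0.53, p=0.593, sig="", p_method="normal"),
    "E": dict(li=50.00, z=1.14, p=0.289, sig="", p_method="exact", z_typo=1.41),
    "F": dict(li=-100.00, z=-2.65, p=0.016, sig="S(L)", p_method="exact"),
    "G": dict(li=-71.43, z=-1.89, p=0.125, sig="", p_method="exact"),
    "H": dict(li=55.56, z=1.67, p=0.180, sig="", p_method="exact"),
    "I": dict(li=-41.18, z=-1.70, p=0.090, sig="", p_method="normal"),
    "J": dict(li=-62.50, z=-2.50, p=0.021, sig="S(L)", p_method="exact"),
    "K": dict(li=-25.00, z=-0.71, p=0.717, sig="", p_method="typo", p_exact=0.727),
    "L": dict(li=-35.48, z=-1.98, p=0.048, sig="S(L)", p_method="normal"),
    "M": dict(li=16.67, z=0.58, p=0.564, sig="", p_method="normal"),
    "N": dict(li=0.00, z=0.00, p=1.000, sig="AMBI", p_method="exact"),
    "O": dict(li=-66.67, z=-2.31, p=0.039, sig="S(L)", p_method="exact"),
    "P": dict(li=42.86, z=1.60, p=0.180, sig="", p_method="exact"),
    "Q": dict(li=-15.38, z=-0.78, p=0.433, sig="", p_method="normal"),
    "R": dict(li=-12.50, z=-0.50, p=0.617, sig="", p_method="normal"),
    "S": dict(li=20.00, z=0.63, p=0.754, sig="", p_method="exact"),
    "T": dict(li=17.65, z=0.73, p=0.467, sig="", p_method="normal"),
    "U": dict(li=-100.00, z=-2.45, p=0.031, sig="S(L)", p_method="exact"),
    "V": dict(li=7.69, z=0.28, p=0.782, sig="", p_method="normal"),
    "W": dict(li=63.64, z=2.11, p=0.065, sig="", p_method="exact"),
    "X": dict(li=17.65, z=0.73, p=0.467, sig="", p_method="normal"),
    "Y": dict(li=42.86, z=1.60, p=0.180, sig="", p_method="exact"),
    "Z": dict(li=-66.67, z=-1.63, p=0.219, sig="", p_method="exact"),
    "AA": dict(li=14.29, z=0.53, p=0.593, sig="", p_method="normal"),
    "AB": dict(li=-33.33, z=-1.00, p=0.508, sig="", p_method="exact"),
    "AC": dict(li=-100.00, z=-2.83, p=0.008, sig="S(L)", p_method="exact"),
    "AD": dict(li=-71.43, z=-1.89, p=0.125, sig="", p_method="exact"),
    "AE": dict(li=55.56, z=1.67, p=0.180, sig="", p_method="exact"),
    "AF": dict(li=-60.00, z=-1.90, p=0.109, sig="", p_method="exact"),
    "AG": dict(li=25.00, z=0.71, p=0.727, sig="", p_method="exact"),
    "AH": dict(li=-5.26, z=-0.23, p=0.819, sig="", p_method="normal"),
    "AI": dict(li=16.67, z=0.58, p=0.564, sig="", p_method="normal"),
    "AJ": dict(li=-16.67, z=-0.58, p=0.564, sig="", p_method="normal"),
    "AK": dict(li=-66.67, z=-1.63, p=0.219, sig="", p_method="exact"),
    "AL": dict(li=42.86, z=1.13, p=0.453, sig="", p_method="exact"),
    "AM": dict(li=11.11, z=0.33, p=1.000, sig="", p_method="exact"),
    "AN": dict(li=60.00, z=1.34, p=0.375, sig="", p_method="exact"),
    "AO": dict(li=42.86, z=1.13, p=0.453, sig="", p_method="exact"),
    "AP": dict(li=-48.94, z=-3.35, p=0.001, sig="S(L)", p_method="normal"),
    "AQ": dict(li=-33.33, z=-1.53, p=0.127, sig="", p_method="normal"),
    "AR": dict(li=55.56, z=1.67, p=0.180, sig="", p_method="exact"),
}


@pytest.fixture(scope="session")
def focal_records():
    return load_focal_fixture()


@pytest.fixture(scope="session")
def focal_results(focal_records):
    return assess_cohort(focal_records)


@pytest.fixture(scope="session")
def printed_table():
    return PRINTED_TABLE
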