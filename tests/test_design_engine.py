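"""Pre-filters, neighborhood search, angular rule, scoring and suggestions."""

import math

import numpy as np
import pandas as pd
import pytest

from saltbridger.bridge_survey import DEFAULT_BIN_EDGES, PairIndex
from saltbridger.design_engine import (
    check_angular_constraint,
    electrostatic_score,
    find_neighbors,
    prefilter_positions,
    suggest_mutations,
    suggestions_to_frame,
)
from saltbridger.reference_data import charge
from tests.conftest import make_residue, structure_from


def _descriptor_frame(rows):
    cols = ["chain", "resnum", "icode", "aa", "rsa", "z_b", "z_rwcn", "conservation"]
    return pd.DataFrame(rows, columns=cols)


def test_prefilter_matches_oracle():
    rows = [
        # engineered to pass every filter
        ("A", 1, "", "N", 0.50, 1.0, 0.5, 2.0),
        ("A", 2, "", "S", 0.40, 0.1, 0.1, 3.0),
        ("A", 3, "", "E", 0.90, 2.0, 2.0, 1.0),
        # single-filter failures
        ("A", 4, "", "L", 0.50, 1.0, 0.5, 2.0),   # hydrophobic type
        ("A", 5, "", "N", 0.30, 1.0, 0.5, 2.0),   # buried
        ("A", 6, "", "N", 0.50, -0.2, 0.5, 2.0),  # rigid
        ("A", 7, "", "N", 0.50, 1.0, -0.5, 2.0),  # well packed
        ("A", 8, "", "N", 0.50, 1.0, 0.5, 7.0),   # conserved
        ("A", 9, "", "N", 0.50, 1.0, 0.5, None),  # no grade -> fails
    ]
    df = _descriptor_frame(rows)
    positions, cascade = prefilter_positions(df)
    # independent oracle: plain boolean mask over the table
    mask = (
        df["aa"].isin(set("STCNQKRDE"))
        & (df["rsa"] > 0.35) & (df["z_b"] > 0) & (df["z_rwcn"] > 0)
        & df["conservation"].notna() & (df["conservation"] < 4)
    )
    expected = [(r["chain"], r["resnum"], r["icode"]) for _, r in df[mask].iterrows()]
    assert positions == expected == [("A", 1, ""), ("A", 2, ""), ("A", 3, "")]
    assert cascade == {
        "polar_or_charged": 8, "rsa": 7, "z_b": 6, "z_rwcn": 5, "conservation": 3,
    }


def test_prefilter_monotone_in_thresholds():
    rng = np.random.default_rng(11)
    rows = [
        ("A", i, "", rng.choice(list("STCNQKRDELAVG")),
         float(rng.uniform(0, 1)), float(rng.normal()), float(rng.normal()),
         float(rng.integers(1, 10)))
        for i in range(1, 60)
    ]
    df = _descriptor_frame(rows)
    base, _ = prefilter_positions(df)
    for kwargs in ({"rsa_min": 0.2}, {"z_b_min": -1.0}, {"z_rwcn_min": -1.0}, {"cons_max": 6}):
        relaxed, _ = prefilter_positions(df, **kwargs)
        assert set(base) <= set(relaxed)


def test_prefilter_unsatisfiable_rsa_empty():
    df = _descriptor_frame([("A", 1, "", "N", 0.50, 1.0, 0.5, 2.0)])
    positions, _ = prefilter_positions(df, rsa_min=10.0)
    assert positions == []


def _charged(chain, resnum, aa, ca, extra=None):
    atoms = {"CA": ca, "CB": np.asarray(ca, float) + [0.5, 1.0, 0]}
    atoms.update(extra or {})
    return make_residue(chain, resnum, aa, atoms)


def test_find_neighbors_radius_boundary():
    pos = make_residue("A", 50, "N", {"CA": [0, 0, 0], "CB": [1, 1, 0]})
    near = _charged("A", 10, "D", [14.9, 0, 0])
    far = _charged("A", 20, "E", [15.1, 0, 0])
    other_chain = _charged("B", 7, "K", [0, 12.0, 0])
    neutral = make_residue("A", 30, "L", {"CA": [5.0, 0, 0], "CB": [5.5, 1, 0]})
    st_ = structure_from([pos, near, far, other_chain, neutral])
    found = find_neighbors(pos, st_)
    keys = {r.key for r, _d in found}
    assert keys == {("A", 10, ""), ("B", 7, "")}


@pytest.mark.parametrize(
    "theta1,theta2,r,expected",
    [
        (150.0, 150.0, 6.5, True),   # rule only applies beyond 7 A
        (120.0, 80.0, 9.0, True),    # one angle under the cutoff suffices
        (120.0, 130.0, 9.0, False),
        (109.9, 130.0, 7.01, True),
        (110.0, 110.0, 7.01, False),  # strict inequality at the cutoff
    ],
)
def test_check_angular_constraint(theta1, theta2, r, expected):
    assert check_angular_constraint(theta1, theta2, r) is expected


def _uniform_index(weight_map=None):
    """Index with hand-set weights for exact scoring checks."""
    weights = weight_map or {
        ("K-D", "H", "C", 5): 12.5, ("R-D", "H", "C", 5): 25.0,
        ("K-E", "H", "H", 5): 10.0, ("R-E", "C", "C", 9): 2.5,
    }
    total = sum(weights.values())
    return PairIndex({k: 100.0 * v / total for k, v in weights.items()},
                     DEFAULT_BIN_EDGES, n_bridges=42)


def test_score_single_opposite_neighbor_is_its_weight():
    idx = _uniform_index()
    w = idx.weight("K-D", "H", "C", 8.5)
    total, per_pair = electrostatic_score("K", "H", [("D", "C", 8.5)], idx)
    assert w > 0 and total == pytest.approx(w) and per_pair == [total]


def test_score_like_charges_contribute_zero():
    idx = _uniform_index()
    total, per_pair = electrostatic_score("K", "H", [("K", "C", 8.5), ("R", "H", 5.0)], idx)
    assert total == 0.0 and per_pair == [0.0, 0.0]


def test_score_matches_exhaustive_oracle_on_random_neighborhoods():
    idx = _uniform_index()
    rng = np.random.default_rng(5)
    aas = list("KRDESTALN")
    for _ in range(50):
        sub = rng.choice(list("KRDE"))
        ss_site = rng.choice(list("HSC"))
        neighbors = [
            (rng.choice(aas), rng.choice(list("HSC")), float(rng.uniform(2.0, 17.0)))
            for _ in range(20)
        ]
        total, per_pair = electrostatic_score(sub, ss_site, neighbors, idx)
        # oracle: independent per-neighbor lookup with its own bin arithmetic
        expected = 0.0
        for aa, ss_nb, r in neighbors:
            if charge(sub) * charge(aa) != -1 or not 3.0 <= r < 15.0:
                continue
            bin_ = int(math.floor(r - 3.0))
            if charge(sub) > 0:
                key = (f"{sub}-{aa}", ss_site, ss_nb, bin_)
            else:
                key = (f"{aa}-{sub}", ss_nb, ss_site, bin_)
            expected += idx.weights.get(key, 0.0)
        assert total == pytest.approx(expected, abs=1e-12)
        assert total == pytest.approx(sum(per_pair), abs=1e-12)


def _design_scene():
    """One polar position, one D partner at 8.5 A (helix site, coil partner)."""
    pos = make_residue("A", 50, "N", {"CA": [0, 0, 0], "CB": [1.53, 0, 0]})
    asp = _charged("A", 60, "D", [8.5, 0, 0], {"CB": [7.5, 1.0, 0]})
    st_ = structure_from([pos, asp])
    ss3 = {("A", 50, ""): "H", ("A", 60, ""): "C"}
    return pos, st_, ss3


def test_single_option_yields_single_suggestion():
    pos, st_, ss3 = _design_scene()
    idx = _uniform_index()
    suggestions, pairs = suggest_mutations([pos.key], st_, idx, ss3)
    assert len(suggestions) == 1
    s = suggestions[0]
    assert s.substitution == "R"  # R-D weight dominates K-D in the index
    assert s.partner == ("A", 60, "") and s.seq_separation == 10
    assert s.score == pytest.approx(idx.weight("R-D", "H", "C", 8.5))
    assert not s.alternative_rule


def test_equal_weights_tie_emits_both_substitutions():
    pos, st_, ss3 = _design_scene()
    idx = _uniform_index({("K-D", "H", "C", 5): 30.0, ("R-D", "H", "C", 5): 30.0})
    suggestions, _ = suggest_mutations([pos.key], st_, idx, ss3)
    assert sorted(s.substitution for s in suggestions) == ["K", "R"]
    assert len({s.score for s in suggestions}) == 1


def test_short_separation_only_position_dropped():
    pos = make_residue("A", 50, "N", {"CA": [0, 0, 0], "CB": [1.53, 0, 0]})
    asp = _charged("A", 53, "D", [8.5, 0, 0], {"CB": [7.5, 1.0, 0]})  # sep 3 < 5
    st_ = structure_from([pos, asp])
    ss3 = {("A", 50, ""): "H", ("A", 53, ""): "C"}
    suggestions, _ = suggest_mutations([pos.key], st_, _uniform_index(), ss3)
    assert suggestions == []


def test_inter_chain_partner_always_satisfies_separation():
    pos = make_residue("A", 50, "N", {"CA": [0, 0, 0], "CB": [1.53, 0, 0]})
    asp = _charged("B", 50, "D", [8.5, 0, 0], {"CB": [7.5, 1.0, 0]})
    st_ = structure_from([pos, asp])
    ss3 = {("A", 50, ""): "H", ("B", 50, ""): "C"}
    suggestions, _ = suggest_mutations([pos.key], st_, _uniform_index(), ss3)
    assert len(suggestions) == 1 and suggestions[0].inter_subunit


def test_alternative_substitution_rule():
    """Global best pair is sequence-local (an E substitution against a nearby
    Arg); the alternative K substitution is adopted because its long-range
    pair outscores K's own (repulsive, zero-weight) local pairing."""
    pos = make_residue("A", 50, "N", {"CA": [0, 0, 0], "CB": [1.53, 0, 0]})
    near_r = _charged("A", 52, "R", [5.0, 0, 0], {"CB": [4.0, 1.0, 0]})
    far_d = _charged("A", 70, "D", [0, 8.5, 0], {"CB": [0.5, 7.5, 0]})
    st_ = structure_from([pos, near_r, far_d])
    ss3 = {("A", 50, ""): "H", ("A", 52, ""): "C", ("A", 70, ""): "H"}
    idx = _uniform_index({
        ("R-E", "C", "H", 2): 50.0,   # dominant but sequence-local: E50-R52
        ("K-D", "H", "H", 5): 30.0,   # alternative long-range: K50-D70
    })
    suggestions, _ = suggest_mutations([pos.key], st_, idx, ss3)
    assert len(suggestions) == 1
    s = suggestions[0]
    assert s.substitution == "K" and s.partner == ("A", 70, "")
    assert s.alternative_rule


def test_alternative_rule_rejects_weaker_long_pair():
    """If the long-range pair scores below the same substitution's local pair,
    nothing is suggested."""
    pos = make_residue("A", 50, "N", {"CA": [0, 0, 0], "CB": [1.53, 0, 0]})
    near_d = _charged("A", 52, "D", [5.0, 0, 0], {"CB": [4.0, 1.0, 0]})
    far_e = _charged("A", 70, "E", [0, 8.5, 0], {"CB": [0.5, 7.5, 0]})
    st_ = structure_from([pos, near_d, far_e])
    ss3 = {("A", 50, ""): "H", ("A", 52, ""): "C", ("A", 70, ""): "H"}
    idx = _uniform_index({
        ("K-D", "H", "C", 2): 50.0,
        ("K-E", "H", "H", 5): 20.0,
        ("R-D", "H", "C", 2): 30.0,
    })
    suggestions, _ = suggest_mutations([pos.key], st_, idx, ss3)
    assert suggestions == []


def test_monotone_in_neighbors():
    """An extra qualifying opposite-charge neighbor never lowers the score;
    a like-charge neighbor never changes it."""
    idx = _uniform_index()
    base = [("D", "C", 8.5)]
    e0, _ = electrostatic_score("K", "H", base, idx)
    e1, _ = electrostatic_score("K", "H", base + [("E", "H", 8.2)], idx)
    e2, _ = electrostatic_score("K", "H", base + [("R", "H", 8.2)], idx)
    assert e1 >= e0
    assert e2 == e0


def test_emitted_suggestions_respect_all_constraints():
    """Randomized scenes: every emitted pair obeys the angular rule beyond
    7 A and the separation-or-interface rule."""
    rng = np.random.default_rng(17)
    idx = _uniform_index()
    all_suggestions = []
    for trial in range(30):
        residues = [make_residue("A", 50, "N", {"CA": [0, 0, 0], "CB": [1.53, 0, 0]})]
        ss3 = {("A", 50, ""): str(rng.choice(list("HSC")))}
        for k in range(6):
            chain = str(rng.choice(["A", "B"]))
            resnum = int(rng.integers(45, 75))
            aa = str(rng.choice(list("KRDE")))
            ca = rng.uniform(-12, 12, 3)
            if any(r.chain_id == chain and r.seq_number == resnum for r in residues):
                continue
            residues.append(_charged(chain, resnum, aa, ca, {"CB": ca + rng.normal(0, 1, 3)}))
            ss3[(chain, resnum, "")] = str(rng.choice(list("HSC")))
        st_ = structure_from(residues)
        suggestions, _ = suggest_mutations([("A", 50, "")], st_, idx, ss3)
        all_suggestions.extend(suggestions)
        for s in suggestions:
            assert s.score > 0
            assert s.seq_separation >= 5 or s.inter_subunit
            if s.ca_distance > 7.0:
                assert min(s.theta1, s.theta2) < 110.0
    assert all_suggestions  # the scenes actually exercise the rules


def test_suggestions_deterministic():
    pos, st_, ss3 = _design_scene()
    idx = _uniform_index()
    frames = [
        suggestions_to_frame(suggest_mutations([pos.key], st_, idx, ss3)[0]).to_csv(sep="\t")
        for _ in range(2)
    ]
    assert frames[0] == frames[1]
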