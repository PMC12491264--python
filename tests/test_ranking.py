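import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pytest

from multioptosis import (
    MetaZTable,
    RankMap,
    rank_signature,
    select_representatives,
    signature_metaz,
    validate_signature,
)
from multioptosis.errors import RankConfigurationError
from multioptosis.ranking import expected_direction_from_hrc


@dataclass
class FakeSig:
    """Minimal signature stand-in for ranking/selection tests."""

    identifier: str = "ACC-1.6.3.P.1.0.0.4.4.1"
    layer: str = "mrna"
    members: list = field(default_factory=lambda: ["G0001"])
    tic: int = 4
    tmc: int = 4
    tnc: int = 1
    hrc_letters: tuple = ("A", "A", "A", "A")
    smc_letters: tuple = ("A", "A", "A", "A")
    rcd_forms: frozenset = frozenset({"apoptosis"})
    rank: int = 0


def test_rank_is_zero_at_minimum_contributions():
    assert rank_signature(FakeSig(), RankMap()) == 0


def test_rank_orders_hot_above_cold_and_counts_letters():
    rm = RankMap()
    hot = FakeSig(tic=1)
    cold = FakeSig(tic=3)
    assert rank_signature(hot, rm) > rank_signature(cold, rm)
    # every non-A letter contributes one point per array
    full = FakeSig(hrc_letters=("B", "B", "B", "B"), smc_letters=("C", "C", "C", "C"))
    assert rank_signature(full, rm) == 8
    informative_tnc = FakeSig(tnc=3)
    assert rank_signature(informative_tnc, rm) == 1


def test_rank_additivity_in_single_components():
    rm = RankMap()
    base = FakeSig(tic=2, tmc=3, tnc=2)
    for tic in (1, 3, 4):
        delta = rank_signature(FakeSig(tic=tic, tmc=3, tnc=2), rm) - rank_signature(base, rm)
        assert delta == rm.tic[tic] - rm.tic[2]


def test_member_bonus_caps_and_ignores_order():
    rm = RankMap()
    assert rank_signature(FakeSig(members=["a", "b", "c"]), rm) == 2
    assert rank_signature(FakeSig(members=[f"g{i}" for i in range(20)]), rm) == 5
    fwd = FakeSig(members=["a", "b", "c"])
    rev = FakeSig(members=["c", "b", "a"])
    assert rank_signature(fwd, rm) == rank_signature(rev, rm)


def test_missing_component_value_raises():
    rm = RankMap(tic={1: 3})
    with pytest.raises(RankConfigurationError):
        rank_signature(FakeSig(tic=2), rm)


def test_rank_map_loads_overrides_from_yaml(tmp_path):
    path = tmp_path / "rank.yaml"
    path.write_text("tic: {1: 10, 2: 0, 3: 0, 4: 0}\nmember_cap: 2\n")
    rm = RankMap.from_file(path)
    assert rank_signature(FakeSig(tic=1), rm) == 10
    assert rank_signature(FakeSig(members=list("abcdef")), rm) == 2


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------


def test_tie_break_prefers_more_members_then_contexture():
    a = FakeSig(identifier="ACC-1.6.3.P.1.0.0.1.1.1", members=["x"], rank=5)
    b = FakeSig(identifier="ACC-2.6.3.P.1.0.0.1.1.1", members=["x", "y", "z"], rank=5)
    picked = select_representatives([a, b], mode="per_rcd_form")
    assert picked == [b]  # member count breaks the rank tie

    c = FakeSig(identifier="ACC-3.6.3.P.1.0.0.1.3.1", members=["x"], rank=5, tic=3)
    d = FakeSig(identifier="ACC-4.6.3.P.1.0.0.1.1.1", members=["x"], rank=5, tic=1)
    assert select_representatives([c, d], mode="per_rcd_form") == [d]  # hot wins


def test_full_tie_falls_back_to_identifier_order():
    a = FakeSig(identifier="ACC-2.6.3.P.1.0.0.4.4.1", rank=5)
    b = FakeSig(identifier="ACC-1.6.3.P.1.0.0.4.4.1", rank=5)
    assert select_representatives([a, b], mode="per_rcd_form") == [b]


def test_selection_is_stable_under_shuffling_and_subset_of_input():
    rng = random.Random(3)
    sigs = [
        FakeSig(identifier=f"ACC-{i}.6.3.P.1.0.0.4.4.1", rank=i % 4,
                rcd_forms=frozenset({f}), layer=l)
        for i, (f, l) in enumerate(
            [("apoptosis", "mrna"), ("necrosis", "mrna"), ("apoptosis", "cnv"),
             ("ferroptosis", "transcript"), ("necrosis", "mutation")] * 2
        )
    ]
    picked = select_representatives(sigs, mode="per_rcd_form")
    assert set(id(s) for s in picked) <= set(id(s) for s in sigs)
    shuffled = sigs[:]
    rng.shuffle(shuffled)
    assert [s.identifier for s in select_representatives(shuffled, "per_rcd_form")] == [
        s.identifier for s in picked
    ]
    ranks = [s.rank for s in picked]
    assert ranks == sorted(ranks, reverse=True)


def test_per_omic_mode_backfills_missing_layers():
    sigs = [
        FakeSig(identifier="ACC-1.6.3.P.1.0.0.4.4.1", layer="mrna", rank=9,
                rcd_forms=frozenset({"apoptosis"})),
        FakeSig(identifier="ACC-2.1.3.P.1.0.0.4.4.1", layer="protein", rank=1,
                rcd_forms=frozenset({"apoptosis"})),
    ]
    picked = select_representatives(sigs, mode="per_omic_feature")
    assert {s.layer for s in picked} == {"mrna", "protein"}
    assert select_representatives([], "per_omic_feature") == []


# ---------------------------------------------------------------------------
# meta-Z validation
# ---------------------------------------------------------------------------


def make_table():
    return MetaZTable(
        pd.DataFrame(
            {"ACC": [4.0, 2.0, 4.5], "BRCA": [np.nan, 3.5, -4.0]},
            index=["g1", "g2", "g3"],
        )
    )


def test_signature_metaz_single_multi_and_missing():
    table = make_table()
    z, excl = signature_metaz(["g1"], "ACC", table)
    assert (z, excl) == (4.0, 0)
    z, excl = signature_metaz(["g1", "g2", "g3"], "ACC", table)
    assert z == 4.0 and excl == 0  # median of {4.0, 2.0, 4.5}
    z, excl = signature_metaz(["g1", "g2"], "BRCA", table)
    assert z == 3.5 and excl == 1  # missing gene excluded and counted
    odd = MetaZTable(pd.DataFrame({"ACC": [2.0, 4.5, 3.5]}, index=["a", "b", "c"]))
    assert signature_metaz(["a", "b", "c"], "ACC", odd)[0] == 3.5  # median by hand
    z, excl = signature_metaz(["nope", "also_nope"], "ACC", table)
    assert math.isnan(z) and excl == 2


def test_validation_thresholds_and_direction():
    assert validate_signature(4.2, "poor") == "validated"
    assert validate_signature(2.5, "poor") == "not_validated"  # below 3.09
    assert validate_signature(-4.0, "poor") == "not_validated"  # direction mismatch
    assert validate_signature(-4.0, "favorable") == "validated"
    assert validate_signature(float("nan"), "poor") == "missing"


def test_validation_antisymmetry():
    for z in (-5.0, -3.2, -1.0, 0.0, 2.0, 3.5, 6.0):
        assert validate_signature(z, "poor") == validate_signature(-z, "favorable")


def test_expected_direction_from_hrc_rules():
    assert expected_direction_from_hrc(("A", "A", "A", "B")) == "poor"  # OS risky wins
    assert expected_direction_from_hrc(("B", "B", "A", "C")) == "favorable"  # OS protective
    assert expected_direction_from_hrc(("B", "B", "C", "A")) == "poor"  # majority
    assert expected_direction_from_hrc(("B", "C", "A", "A")) is None  # unresolved
    assert expected_direction_from_hrc(("A", "A", "A", "A")) is None


def test_metaz_table_round_trips_tsv(tmp_path):
    table = make_table()
    path = tmp_path / "metaz.tsv"
    table.to_tsv(path)
    back = MetaZTable.from_tsv(path)
    assert back.lookup("g1", "ACC") == 4.0
    assert math.isnan(back.lookup("g1", "BRCA"))
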