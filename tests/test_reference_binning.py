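from collections import Counter
from itertools import permutations, product

import pytest

from magcurate.formats_io import NOBIN, BinQCRecord, load_taxonomy
from magcurate.reference_binning import (
    PRESET_ORDER,
    PRESETS,
    bin_contigs,
    merge_advisory,
    quality_tier,
    select_preset,
)

from conftest import make_contig, random_dna


# -- presets -----------------------------------------------------------------


def test_preset_thresholds_strictly_decrease():
    tnf = [PRESETS[n].tnf_threshold for n in PRESET_ORDER]
    cov = [PRESETS[n].coverage_log_threshold for n in PRESET_ORDER]
    assert tnf == sorted(tnf, reverse=True) and len(set(tnf)) == len(tnf)
    assert cov == sorted(cov, reverse=True) and len(set(cov)) == len(cov)


# -- bin_contigs -------------------------------------------------------------


def _accuracy(result, truth_map):
    bins = result.bins()
    bin_genome = {}
    for b, members in bins.items():
        if b == NOBIN:
            continue
        counts = Counter(truth_map[m].genome for m in members)
        bin_genome[b] = counts.most_common(1)[0][0]
    correct = total = 0
    for cid, t in truth_map.items():
        if t.is_rrna_contig:
            continue
        total += 1
        b = result.assignments[cid]
        if b != NOBIN and bin_genome[b] == t.genome:
            correct += 1
    return correct / total


def test_missing_depth_is_error(rng):
    contigs = [make_contig("c1", random_dna(rng, 3000), depth=5.0)]
    with pytest.raises(KeyError, match="c1"):
        bin_contigs(contigs, {}, PRESETS["specific"])


def test_short_contigs_go_to_nobin(rng):
    contigs = [
        make_contig("short", random_dna(rng, 1000), depth=5.0),
        make_contig("long", random_dna(rng, 60_000), depth=5.0),
    ]
    depths = {c.id: c.depth for c in contigs}
    result = bin_contigs(contigs, depths, PRESETS["specific"])
    assert result.assignments["short"] == NOBIN
    assert result.assignments["long"] == "bin1"


def test_one_genome_single_bin(demo_community, demo_depths):
    contigs, truth, _ = demo_community
    g_low = [c for c in contigs if c.id.startswith("g_low")]
    depths = {c.id: demo_depths[c.id] for c in g_low}
    for name in PRESET_ORDER:
        result = bin_contigs(g_low, depths, PRESETS[name])
        bins = result.bins()
        binned_len = sum(
            c.length for c in g_low if result.assignments[c.id] != NOBIN
        )
        assert binned_len / sum(c.length for c in g_low) >= 0.95
        assert len([b for b in bins if b != NOBIN]) == 1


def test_two_genome_demo_accuracy(demo_community, demo_depths):
    contigs, truth, _ = demo_community
    truth_map = {t.contig_id: t for t in truth}
    for name in PRESET_ORDER:
        result = bin_contigs(contigs, demo_depths, PRESETS[name])
        n_real_bins = len([b for b in result.bins() if b != NOBIN])
        assert n_real_bins == 2, name
        assert _accuracy(result, truth_map) >= 0.95, name


def test_rrna_contig_unbinned_under_all_presets(demo_community, demo_depths):
    contigs, truth, _ = demo_community
    (rrna_id,) = [
        t.contig_id for t in truth if t.is_rrna_contig
    ]
    for name in PRESET_ORDER:
        result = bin_contigs(contigs, demo_depths, PRESETS[name])
        assert result.assignments[rrna_id] == NOBIN, name


def test_partition_property(demo_community, demo_depths):
    contigs, _, _ = demo_community
    result = bin_contigs(contigs, demo_depths, PRESETS["sensitive"])
    assert set(result.assignments) == {c.id for c in contigs}
    # dict-of-contig->bin is a partition by construction; check bin sizes sum
    assert sum(len(v) for v in result.bins().values()) == len(contigs)


def test_monotonicity_across_presets(demo_community, demo_depths):
    contigs, _, _ = demo_community
    n_binned = [
        bin_contigs(contigs, demo_depths, PRESETS[name]).n_binned()
        for name in PRESET_ORDER
    ]
    assert n_binned == sorted(n_binned, reverse=True)


def test_bins_numbered_by_decreasing_length(demo_community, demo_depths):
    contigs, _, _ = demo_community
    result = bin_contigs(contigs, demo_depths, PRESETS["veryspecific"])
    lengths = {c.id: c.length for c in contigs}
    bins = result.bins()
    totals = [
        sum(lengths[m] for m in bins[b])
        for b in sorted(b for b in bins if b != NOBIN)
    ]
    assert totals == sorted(totals, reverse=True)


# -- select_preset -----------------------------------------------------------


def _qc(contamination, heterogeneity, completeness, bin_id="bin1"):
    return BinQCRecord(
        strain="S",
        bin_id=bin_id,
        taxon="Bacteria",
        nature="M",
        n_scaffolds=10,
        length_pct=50.0,
        coverage_med=10.0,
        completeness=completeness,
        contamination=contamination,
        strain_heterogeneity=heterogeneity,
    )


def test_contamination_dominates():
    tables = {
        "sensitive": [_qc(1.0, 0.0, 95.0)],
        "specific": [_qc(0.5, 50.0, 80.0)],
    }
    assert select_preset(tables) == "specific"


def test_heterogeneity_breaks_contamination_tie():
    tables = {
        "sensitive": [_qc(0.5, 10.0, 95.0)],
        "specific": [_qc(0.5, 0.0, 80.0)],
    }
    assert select_preset(tables) == "specific"


def test_completeness_breaks_remaining_tie():
    tables = {
        "sensitive": [_qc(0.5, 0.0, 80.0)],
        "specific": [_qc(0.5, 0.0, 95.0)],
    }
    assert select_preset(tables) == "specific"


def test_next_largest_bin_breaks_exact_tie():
    tables = {
        "sensitive": [_qc(0.5, 0.0, 90.0), _qc(2.0, 0.0, 50.0, "bin2")],
        "specific": [_qc(0.5, 0.0, 90.0), _qc(0.3, 0.0, 50.0, "bin2")],
    }
    assert select_preset(tables) == "specific"


def test_full_tie_returns_more_sensitive():
    tables = {
        "superspecific": [_qc(0.5, 0.0, 90.0)],
        "verysensitive": [_qc(0.5, 0.0, 90.0)],
    }
    assert select_preset(tables) == "verysensitive"


def test_order_invariance():
    tables = {
        "verysensitive": [_qc(1.0, 0.0, 95.0)],
        "specific": [_qc(0.5, 5.0, 85.0)],
        "superspecific": [_qc(0.5, 5.0, 80.0)],
    }
    answers = set()
    for perm in permutations(tables.items()):
        answers.add(select_preset(dict(perm)))
    assert answers == {"specific"}


def test_empty_tables_excluded_then_error():
    with pytest.warns(UserWarning):
        assert (
            select_preset({"sensitive": [], "specific": [_qc(0.5, 0, 90.0)]})
            == "specific"
        )
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError):
            select_preset({"sensitive": [], "specific": []})


def test_select_preset_vs_brute_force_comparator():
    """Exhaustive 3-preset toy tables against an independently written
    recursive comparator."""

    def better(a, b):
        # comparator straight from the rule: walk bins largest-first,
        # compare (contamination asc, heterogeneity asc, completeness desc)
        for ra, rb in zip(a, b):
            ka = (ra.contamination, ra.strain_heterogeneity, -ra.completeness)
            kb = (rb.contamination, rb.strain_heterogeneity, -rb.completeness)
            if ka != kb:
                return -1 if ka < kb else 1
        if len(a) != len(b):
            return -1 if len(a) < len(b) else 1
        return 0

    values = [
        [_qc(0.0, 0.0, 90.0)],
        [_qc(1.0, 0.0, 90.0)],
        [_qc(0.0, 5.0, 90.0)],
        [_qc(0.0, 0.0, 50.0)],
        [_qc(0.0, 0.0, 90.0), _qc(1.0, 0.0, 40.0, "bin2")],
        [_qc(0.0, 0.0, 90.0), _qc(0.2, 0.0, 40.0, "bin2")],
    ]
    names = ("verysensitive", "specific", "superspecific")
    for combo in product(range(len(values)), repeat=3):
        tables = {n: values[i] for n, i in zip(names, combo)}
        got = select_preset(tables)
        # brute force: best table, ties to the more sensitive name
        best = None
        for name in names:  # PRESET_ORDER prefix: sensitivity order
            if best is None or better(tables[name], tables[best]) < 0:
                best = name
        assert got == best, combo


# -- merge_advisory ----------------------------------------------------------


@pytest.fixture(scope="module")
def taxonomy():
    return load_taxonomy()


def test_merge_nested_taxa(taxonomy):
    advice = merge_advisory(
        "Alphaproteobacteria", "Sphingomonadales", True, taxonomy
    )
    assert advice.merge


def test_no_merge_unclassified(taxonomy):
    advice = merge_advisory("Sphingomonadales", "Unclassified", True, taxonomy)
    assert not advice.merge
    assert "unclassified" in advice.reason.lower()


def test_no_merge_without_complementarity(taxonomy):
    advice = merge_advisory(
        "Alphaproteobacteria", "Sphingomonadales", False, taxonomy
    )
    assert not advice.merge
    assert "complementary" in advice.reason


def test_no_merge_disjoint_taxa(taxonomy):
    advice = merge_advisory("Cyanobacteria", "Bacteroidetes", True, taxonomy)
    assert not advice.merge


def test_merge_symmetric(taxonomy):
    a = merge_advisory("Alphaproteobacteria", "Rhizobiales", True, taxonomy)
    b = merge_advisory("Rhizobiales", "Alphaproteobacteria", True, taxonomy)
    assert a.merge == b.merge == True  # noqa: E712


# -- quality_tier ------------------------------------------------------------


def _qc_tier(completeness, contamination):
    return _qc(contamination, 0.0, completeness)


def test_tier_high_with_rrna():
    assert quality_tier(_qc_tier(98.11, 0.0), True) == "high"


def test_tier_low():
    assert quality_tier(_qc_tier(24.14, 1.72), True) == "low"


def test_tier_medium_boundary():
    assert quality_tier(_qc_tier(90.0, 4.99), False) == "medium"
    assert quality_tier(_qc_tier(89.99, 0.0), False) == "low"
    assert quality_tier(_qc_tier(95.0, 5.0), False) == "low"


def test_tier_missing_completeness_errors():
    record = _qc(0.0, 0.0, 90.0)
    record.completeness = None
    with pytest.raises(ValueError):
        quality_tier(record, False)
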