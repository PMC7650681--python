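"""Variant cascade, pathway panels, germline flag, cohort summaries."""

from __future__ import annotations

import pandas as pd
import pytest

from ibcscars import (
    PanelConfig,
    VariantRecord,
    classify_pathway,
    filter_variant,
    flag_potentially_germline,
    load_printed_cohort,
    read_variant_table,
    read_vcf,
    simulate_variant_table,
    summarize_cohort,
)


def rec(**kw):
    base = dict(
        sample="S1",
        gene="BRCA2",
        hgvs_c="c.100A>T",
        consequence="missense",
        region="exonic",
    )
    base.update(kw)
    return VariantRecord(**base)


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kw,verdict,rule",
    [
        # (a) excluded classes, even when otherwise qualifying
        (dict(consequence="synonymous", clin_class={"clinvar": "pathogenic"}),
         "drop", "excluded_class"),
        (dict(region="utr3"), "drop", "excluded_class"),
        (dict(region="intronic"), "drop", "excluded_class"),
        (dict(homopolymer=True), "drop", "excluded_class"),
        # (b) rarity gate beats clinical evidence
        (dict(pop_af={"gnomad": 0.02}, clin_class={"clinvar": "pathogenic"}),
         "drop", "not_rare"),
        (dict(pop_af={"gnomad": 0.005, "abraom": 0.5}), "drop", "not_rare"),
        # (c) clinical pathogenic / likely pathogenic
        (dict(clin_class={"clinvar": "pathogenic"}), "keep", "clinical_pathogenic"),
        (dict(clin_class={"acmg": "likely_pathogenic"}, pop_af={"gnomad": 0.001}),
         "keep", "clinical_pathogenic"),
        # (d) ACMG VUS with loss of function
        (dict(consequence="frameshift", clin_class={"acmg": "vus"}),
         "keep", "vus_lof"),
        (dict(consequence="canonical_splice", clin_class={"acmg": "vus"}),
         "keep", "vus_lof"),
        # VUS without LOF, or no evidence at all -> drop
        (dict(consequence="missense", clin_class={"acmg": "vus"}),
         "drop", "no_evidence"),
        (dict(), "drop", "no_evidence"),
        # LOF alone without an ACMG VUS call is not rule (d)
        (dict(consequence="frameshift"), "drop", "no_evidence"),
    ],
)
def test_cascade_verdicts(kw, verdict, rule):
    d = filter_variant(rec(**kw))
    assert (d.verdict, d.rule_fired) == (verdict, rule)


def test_unknown_consequence_lists_accepted_labels():
    with pytest.raises(ValueError, match="stopgain"):
        filter_variant(rec(consequence="nonsense_mediated"))


def test_cascade_is_deterministic_and_order_free():
    records = [
        rec(sample=f"S{i}", consequence=c, clin_class=cc)
        for i, (c, cc) in enumerate(
            [
                ("missense", {"clinvar": "pathogenic"}),
                ("frameshift", {"acmg": "vus"}),
                ("synonymous", {}),
                ("missense", {}),
            ]
        )
    ]
    forward = [filter_variant(r) for r in records]
    backward = [filter_variant(r) for r in reversed(records)]
    assert [d.verdict for d in forward] == [d.verdict for d in reversed(backward)]


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def test_default_panel_sizes():
    panel = PanelConfig.default()
    assert len(panel.hr_genes) == 13
    assert len(panel.mmr_genes) == 6
    assert len(panel.panel) == 105
    assert not panel.hr_genes & panel.mmr_genes


@pytest.mark.parametrize(
    "gene,pathway",
    [("BRCA2", "HR"), ("RAD51D", "HR"), ("PMS2", "MMR"), ("msh6", "MMR"),
     ("TP53", "other"), ("PIK3CA", "other")],
)
def test_classify_pathway(gene, pathway):
    assert classify_pathway(gene) == pathway


def test_overlapping_hr_mmr_sets_rejected():
    with pytest.raises(ValueError, match="disjoint"):
        PanelConfig(
            hr_genes=frozenset({"BRCA2", "MLH1"}),
            mmr_genes=frozenset({"MLH1"}),
            panel=frozenset({"BRCA2", "MLH1"}),
        )


# ---------------------------------------------------------------------------
# potentially-germline flag
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "vaf,direction,expected",
    [
        (0.30, "below", True),          # printed rule: VAF < 0.5
        (0.50, "below", False),         # strict boundary
        (0.55, "below", False),
        (0.55, "above_or_near", True),  # configured alternative
        (None, "below", None),
    ],
)
def test_flag_potentially_germline(vaf, direction, expected):
    assert flag_potentially_germline(vaf, direction=direction) is expected


# ---------------------------------------------------------------------------
# cohort summary on the printed table
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def printed_summary():
    return summarize_cohort(load_printed_cohort())


def test_printed_table_gene_counts(printed_summary):
    counts = printed_summary.gene_case_counts
    assert counts["TP53"] == 11
    assert counts["BRCA2"] == 8
    assert counts["PIK3CA"] == 5


def test_printed_table_pathway_counts(printed_summary):
    assert printed_summary.pathway_case_counts["HR"] == 13
    assert printed_summary.pathway_case_counts["MMR"] == 8


def test_printed_table_recurrent_variant(printed_summary):
    rec_tab = printed_summary.recurrent_variants
    row = rec_tab[(rec_tab["gene"] == "PIK3CA") & (rec_tab["hgvs_c"] == "c.3140A>G")]
    assert len(row) == 1 and int(row["n_cases"].iloc[0]) == 2


def test_summary_invariant_under_duplication():
    df = load_printed_cohort()
    doubled = pd.concat([df, df], ignore_index=True)
    a = summarize_cohort(df)
    b = summarize_cohort(doubled)
    assert a.gene_case_counts.equals(b.gene_case_counts)
    assert a.pathway_case_counts == b.pathway_case_counts


def test_multiple_variants_one_sample_count_once():
    df = pd.DataFrame(
        {
            "sample": ["S1", "S1"],
            "gene": ["BRCA2", "BRCA2"],
            "hgvs_c": ["c.1A>T", "c.2A>T"],
        }
    )
    s = summarize_cohort(df)
    assert s.gene_case_counts["BRCA2"] == 1
    assert s.pathway_case_counts["HR"] == 1


# ---------------------------------------------------------------------------
# simulated tables and readers
# ---------------------------------------------------------------------------

def test_simulated_verdicts_recovered_exactly():
    records, truth = simulate_variant_table(n_samples=15, seed=11)
    got = [filter_variant(r).verdict for r in records]
    assert got == truth.truth["verdicts"]


def test_simulated_pure_classes():
    recs, truth = simulate_variant_table(
        n_samples=5, class_mix={"synonymous": 1.0}, seed=2
    )
    assert all(v == "drop" for v in truth.truth["verdicts"])
    assert all(filter_variant(r).verdict == "drop" for r in recs)
    recs, truth = simulate_variant_table(n_samples=5, class_mix={"PLP": 1.0}, seed=2)
    assert all(filter_variant(r).verdict == "keep" for r in recs)


def test_read_variant_table_roundtrip(tmp_path):
    p = tmp_path / "variants.tsv"
    p.write_text(
        "sample\tgene\thgvs_c\tconsequence\tregion\tvaf\tgnomad_af\tacmg\n"
        "S1\tBRCA2\tc.1A>T\tframeshift\texonic\t0.4\t\tvus\n"
        "S2\tTP53\tc.2C>G\tmissense\texonic\t0.6\t0.05\t\n"
    )
    records = read_variant_table(p)
    assert records[0].pop_af == {}
    assert records[0].clin_class == {"acmg": "vus"}
    assert filter_variant(records[0]).verdict == "keep"
    assert records[1].pop_af == {"gnomad": 0.05}
    assert filter_variant(records[1]).verdict == "drop"


def test_read_minimal_vcf(tmp_path):
    p = tmp_path / "mini.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="c">\n'
        '##INFO=<ID=ACMG,Number=1,Type=String,Description="a">\n'
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="v">\n'
        "##contig=<ID=chr13>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr13\t32900000\t.\tA\tT\t.\t.\tGENE=BRCA2;CSQ=stopgain;ACMG=vus;VAF=0.41\n"
    )
    (record,) = read_vcf(p)
    assert record.gene == "BRCA2"
    assert record.consequence == "stopgain"
    assert filter_variant(record).verdict == "keep"
    assert flag_potentially_germline(record) is True
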