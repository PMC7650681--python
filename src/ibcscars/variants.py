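"""Targeted-sequencing variant selection cascade and pathway summaries.

The cascade mirrors a targeted-panel curation workflow:

a. *excluded classes* — synonymous changes, UTR/intronic/intergenic
   variants and homopolymer artefacts are dropped outright;
b. *rarity gate* — a variant must be rare (<1%) in every population
   database where it is observed (gnomAD, ABraOM); absence counts as rare;
c. *clinical evidence* — kept if any clinical source (ACMG, ClinVar,
   Clinvitae) classifies it pathogenic or likely pathogenic;
d. *VUS with loss of function* — kept if the ACMG class is VUS and the
   consequence is frameshift, stopgain or canonical splice site;
e. everything else is dropped.

Exactly one rule fires per record, so verdicts are order-deterministic.

Pathway classification uses a 13-gene homologous-recombination set and a
6-gene mismatch-repair set inside a 105-gene panel.  The printed variant
table of the source cohort (21 tumors) ships as a fixture for
regression-testing the cohort summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "FilterDecision",
    "PanelConfig",
    "CohortSummary",
    "filter_variant",
    "classify_pathway",
    "flag_potentially_germline",
    "summarize_cohort",
    "read_variant_table",
    "read_vcf",
    "load_printed_cohort",
]

CONSEQUENCES = frozenset(
    {"missense", "frameshift", "stopgain", "canonical_splice",
     "synonymous", "inframe_indel", "other"}
)
LOF_CONSEQUENCES = frozenset({"frameshift", "stopgain", "canonical_splice"})
REGIONS = frozenset({"exonic", "utr3", "utr5", "intronic", "intergenic"})
EXCLUDED_REGIONS = frozenset({"utr3", "utr5", "intronic", "intergenic"})
CLIN_CLASSES = frozenset(
    {"pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign", "absent"}
)
PATHOGENIC_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})

RARE_AF_MAX = 0.01   # stated rarity threshold (<0.01)

#: cascade rule identifiers, in firing order
RULES = (
    "excluded_class",
    "not_rare",
    "clinical_pathogenic",
    "vus_lof",
    "no_evidence",
)


@dataclass(frozen=True)
class VariantRecord:
    sample: str
    gene: str
    hgvs_c: str
    consequence: str
    hgvs_p: Optional[str] = None
    region: str = "exonic"
    homopolymer: bool = False
    vaf: Optional[float] = None
    #: database -> population allele frequency (absent databases omitted)
    pop_af: Mapping[str, float] = field(default_factory=dict)
    #: source -> clinical classification (e.g. {"acmg": "vus"})
    clin_class: Mapping[str, str] = field(default_factory=dict)
    cn_context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.vaf is not None and not 0 <= self.vaf <= 1:
            raise ValueError(f"vaf {self.vaf} outside [0,1]")
        for db, af in self.pop_af.items():
            if not 0 <= af <= 1:
                raise ValueError(f"{db} frequency {af} outside [0,1]")


@dataclass(frozen=True)
class FilterDecision:
    verdict: str          # "keep" | "drop"
    rule_fired: str       # member of RULES
    rationale: str

    def __post_init__(self) -> None:
        assert self.verdict in ("keep", "drop")
        assert self.rule_fired in RULES


def filter_variant(record: VariantRecord) -> FilterDecision:
    """Run one record through the selection cascade (first decisive rule wins)."""
    if record.consequence not in CONSEQUENCES:
        raise ValueError(
            f"unknown consequence {record.consequence!r}; "
            f"accepted: {sorted(CONSEQUENCES)}"
        )
    if record.region not in REGIONS:
        raise ValueError(
            f"unknown region {record.region!r}; accepted: {sorted(REGIONS)}"
        )
    # (a) excluded classes
    if record.consequence == "synonymous":
        return FilterDecision("drop", "excluded_class", "synonymous variant")
    if record.region in EXCLUDED_REGIONS:
        return FilterDecision("drop", "excluded_class", f"{record.region} region")
    if record.homopolymer:
        return FilterDecision("drop", "excluded_class", "homopolymer region")
    # (b) rarity gate: every available frequency must be < 0.01
    for db, af in record.pop_af.items():
        if af >= RARE_AF_MAX:
            return FilterDecision(
                "drop", "not_rare", f"{db} frequency {af:g} >= {RARE_AF_MAX}"
            )
    # (c) clinical pathogenic / likely pathogenic in any source
    for source, cls in record.clin_class.items():
        if cls not in CLIN_CLASSES:
            raise ValueError(
                f"unknown clinical class {cls!r} from {source}; "
                f"accepted: {sorted(CLIN_CLASSES)}"
            )
        if cls in PATHOGENIC_CLASSES:
            return FilterDecision(
                "keep", "clinical_pathogenic", f"{source}: {cls}"
            )
    # (d) ACMG VUS with loss-of-function consequence
    if (
        record.clin_class.get("acmg") == "vus"
        and record.consequence in LOF_CONSEQUENCES
    ):
        return FilterDecision(
            "keep", "vus_lof", f"ACMG VUS with {record.consequence}"
        )
    return FilterDecision("drop", "no_evidence", "no qualifying evidence")


# ---------------------------------------------------------------------------
# panel configuration
# ---------------------------------------------------------------------------

def _read_gene_list(path: Path) -> list[str]:
    genes = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.upper())
    return genes


@dataclass(frozen=True)
class PanelConfig:
    hr_genes: frozenset[str]
    mmr_genes: frozenset[str]
    panel: frozenset[str]

    def __post_init__(self) -> None:
        if self.hr_genes & self.mmr_genes:
            raise ValueError("HR and MMR gene sets must be disjoint")
        if not (self.hr_genes <= self.panel and self.mmr_genes <= self.panel):
            raise ValueError("HR and MMR sets must be subsets of the panel")

    @classmethod
    def default(cls) -> "PanelConfig":
        """Shipped configuration: 13 HR + 6 MMR genes inside a 105-gene panel.

        The HR and MMR sets are the published pathway lists; the remaining
        panel genes are a representative stand-in (the full published panel
        is not redistributed) and can be replaced via :meth:`from_files`.
        """
        data = resources.files("ibcscars") / "data"
        return cls.from_files(
            data / "hr_genes.txt", data / "mmr_genes.txt", data / "panel_genes.txt"
        )

    @classmethod
    def from_files(cls, hr_path, mmr_path, panel_path) -> "PanelConfig":
        return cls(
            hr_genes=frozenset(_read_gene_list(Path(str(hr_path)))),
            mmr_genes=frozenset(_read_gene_list(Path(str(mmr_path)))),
            panel=frozenset(_read_gene_list(Path(str(panel_path)))),
        )


def classify_pathway(gene: str, panel: PanelConfig | None = None) -> str:
    """Return ``"HR"``, ``"MMR"`` or ``"other"`` for a gene symbol."""
    panel = panel or PanelConfig.default()
    g = gene.strip().upper()
    if g in panel.hr_genes:
        return "HR"
    if g in panel.mmr_genes:
        return "MMR"
    return "other"


def flag_potentially_germline(
    record: VariantRecord | float | None,
    threshold: float = 0.5,
    direction: str = "below",
) -> Optional[bool]:
    """Potentially-germline flag from the variant allele fraction.

    The default rule flags VAF strictly below *threshold* (0.5), exactly
    as the source table prints it.  ``direction="above_or_near"`` flags
    VAF >= threshold instead, for users who prefer the conventional
    heterozygous-germline reading.  Missing VAF -> None (unknown).
    """
    vaf = record.vaf if isinstance(record, VariantRecord) else record
    if vaf is None:
        return None
    if direction == "below":
        return vaf < threshold
    if direction == "above_or_near":
        return vaf >= threshold
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    #: gene -> number of distinct cases carrying >=1 kept variant in it
    gene_case_counts: pd.Series
    #: pathway ("HR"/"MMR") -> distinct-case count
    pathway_case_counts: dict[str, int]
    #: (gene, hgvs_c) recurrent in >=2 cases, with their case counts
    recurrent_variants: pd.DataFrame
    #: sample x {"HR","MMR"} boolean variant-status flags
    sample_pathway_status: pd.DataFrame
    n_samples: int


def _to_frame(records: Iterable[VariantRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {"sample": r.sample, "gene": r.gene, "hgvs_c": r.hgvs_c}
                for r in records
            ]
        )
    for col in ("sample", "gene", "hgvs_c"):
        if col not in df.columns:
            raise ValueError(f"records need a {col!r} column")
    df["gene"] = df["gene"].str.upper()
    return df.drop_duplicates(subset=["sample", "gene", "hgvs_c"])


def summarize_cohort(
    records: Iterable[VariantRecord] | pd.DataFrame,
    panel: PanelConfig | None = None,
) -> CohortSummary:
    """Distinct-case counts per gene and pathway, plus recurrent variants.

    A case counts once per gene / pathway however many qualifying variants
    it carries; duplicated (sample, gene, hgvs_c) records are collapsed.
    """
    panel = panel or PanelConfig.default()
    df = _to_frame(records)
    gene_counts = (
        df.groupby("gene")["sample"].nunique().sort_values(ascending=False)
    )
    df["pathway"] = df["gene"].map(lambda g: classify_pathway(g, panel))
    pathway_counts = {
        pw: int(df.loc[df["pathway"] == pw, "sample"].nunique())
        for pw in ("HR", "MMR")
    }
    rec = (
        df.groupby(["gene", "hgvs_c"])["sample"]
        .nunique()
        .reset_index(name="n_cases")
    )
    rec = rec[rec["n_cases"] >= 2].sort_values(
        ["n_cases", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    samples = sorted(df["sample"].unique())
    status = pd.DataFrame(
        {
            pw: [
                bool(
                    ((df["sample"] == s) & (df["pathway"] == pw)).any()
                )
                for s in samples
            ]
            for pw in ("HR", "MMR")
        },
        index=pd.Index(samples, name="sample"),
    )
    return CohortSummary(
        gene_case_counts=gene_counts,
        pathway_case_counts=pathway_counts,
        recurrent_variants=rec,
        sample_pathway_status=status,
        n_samples=len(samples),
    )


# ---------------------------------------------------------------------------
# readers and fixtures
# ---------------------------------------------------------------------------

_CLIN_SOURCES = ("acmg", "clinvar", "clinvitae")
_AF_SOURCES = ("gnomad_af", "abraom_af")


def read_variant_table(path) -> list[VariantRecord]:
    """Read an annotated-variant TSV into records.

    Required columns: sample, gene, hgvs_c, consequence.  Recognized
    optional columns: hgvs_p, region, homopolymer (0/1), vaf, gnomad_af,
    abraom_af, acmg, clinvar, clinvitae, cn_context.  Empty cells mean
    "absent".
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("sample", "gene", "hgvs_c", "consequence")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for row in df.to_dict("records"):
        pop_af = {}
        for col in _AF_SOURCES:
            val = row.get(col)
            if val is not None and not pd.isna(val) and str(val) != "":
                pop_af[col.removesuffix("_af")] = float(val)
        clin = {}
        for col in _CLIN_SOURCES:
            val = row.get(col)
            if val is not None and not pd.isna(val) and str(val) != "":
                clin[col] = str(val)
        vaf = row.get("vaf")
        vaf = None if vaf is None or pd.isna(vaf) or str(vaf) == "" else float(vaf)
        hp = row.get("homopolymer", "0")
        records.append(
            VariantRecord(
                sample=str(row["sample"]),
                gene=str(row["gene"]),
                hgvs_c=str(row["hgvs_c"]),
                hgvs_p=None if pd.isna(row.get("hgvs_p")) else row.get("hgvs_p"),
                consequence=str(row["consequence"]),
                region=str(row.get("region") or "exonic"),
                homopolymer=str(hp) in ("1", "True", "true"),
                vaf=vaf,
                pop_af=pop_af,
                clin_class=clin,
                cn_context=None
                if pd.isna(row.get("cn_context"))
                else row.get("cn_context"),
            )
        )
    return records


#: default mapping from VCF INFO keys to record fields
DEFAULT_VCF_KEY_MAP = {
    "gene": "GENE",
    "hgvs_c": "HGVSC",
    "hgvs_p": "HGVSP",
    "consequence": "CSQ",
    "region": "REGION",
    "homopolymer": "HOMOPOL",
    "vaf": "VAF",
    "gnomad": "GNOMAD_AF",
    "abraom": "ABRAOM_AF",
    "acmg": "ACMG",
    "clinvar": "CLINVAR",
    "clinvitae": "CLINVITAE",
}


def read_vcf(path, key_map: Mapping[str, str] | None = None) -> list[VariantRecord]:
    """Read a minimal single-sample VCF whose INFO keys carry annotations."""
    from cyvcf2 import VCF

    km = dict(DEFAULT_VCF_KEY_MAP)
    if key_map:
        km.update(key_map)
    vcf = VCF(str(path))
    sample = vcf.samples[0] if vcf.samples else Path(str(path)).stem
    records = []
    for v in vcf:
        info = {k: v.INFO.get(km[k]) for k in km}
        pop_af = {
            db: float(info[db]) for db in ("gnomad", "abraom") if info.get(db) is not None
        }
        clin = {
            src: str(info[src]) for src in _CLIN_SOURCES if info.get(src) is not None
        }
        records.append(
            VariantRecord(
                sample=sample,
                gene=str(info.get("gene") or "."),
                hgvs_c=str(info.get("hgvs_c") or f"c.{v.POS}{v.REF}>{v.ALT[0]}"),
                hgvs_p=info.get("hgvs_p"),
                consequence=str(info.get("consequence") or "other"),
                region=str(info.get("region") or "exonic"),
                homopolymer=str(info.get("homopolymer") or "0") in ("1", "True"),
                vaf=None if info.get("vaf") is None else float(info["vaf"]),
                pop_af=pop_af,
                clin_class=clin,
            )
        )
    return records


def load_printed_cohort() -> pd.DataFrame:
    """The variant table of the 21-tumor source cohort, as printed.

    Columns: sample, gene, hgvs_c, hgvs_p, pg (potentially-germline flag,
    VAF < 0.5), cn_context.  These are post-filter (kept) variants in
    TP53, PIK3CA and the HR/MMR pathway genes; two sequenced cases carried
    none.  Used as ground truth for :func:`summarize_cohort`.
    """
    data = resources.files("ibcscars") / "data" / "printed_variant_table.tsv"
    with resources.as_file(data) as p:
        return pd.read_csv(p, sep="\t", dtype=str).fillna("")
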