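"""Built-in reference data for the *Tuber borchii* SP1 worked examples.

These are the published desk-scale numbers for the four submerged-culture
transcriptomes of the T. borchii SP1 strain (media WPG, WPGY, PDB, MPY,
mapped against the 12,346-gene Tbo3840 reference catalog):

* the ten most expressed genes per sample with their per-million values
  and function labels (a *partial* matrix — effort computations against it
  must use the true total of 10^6);
* the per-sample read totals, expressed-gene counts and KOG-annotated
  counts, plus the genome-wide reference row;
* the seven secondary-metabolite (NRPS/PKS) cluster protein IDs.

`reference_gene_sets` additionally packages the central-metabolism and
aroma panels at their published cardinalities (glycolysis 43, TCA 25, ETC
11, glyoxylate 3, aroma 92).  Only a handful of member protein IDs were
published for those panels; the remaining members are synthetic placeholder
IDs (clearly marked with ``synthetic`` in the ID) so the collection has the
right sizes and overlap structure for fixtures and demos.
"""

from __future__ import annotations

import pandas as pd

from .expression_io import (
    PER_MILLION,
    ExpressionMatrix,
    GeneSetCollection,
    make_gene_sets,
)

#: Top-10 most expressed genes per sample: (gene_id, per-million value, function).
TOP10_GENES: dict[str, list[tuple[str, float, str]]] = {
    "WPG": [
        ("990338", 59710.6, "Molecular chaperone"),
        ("1125059", 37904.9, "N/A"),
        ("985714", 19175.7, "N/A"),
        ("986569", 18513.8, "N/A"),
        ("907400", 15291.6, "N/A"),
        ("1138063", 12188.2, "N/A"),
        ("1039918", 11559.9, "Molecular chaperone"),
        ("1067414", 9526.58, "N/A"),
        ("961630", 9394.31, "Histone H4"),
        ("1124376", 9124.24, "Histones H3 and H4"),
    ],
    "WPGY": [
        ("990338", 59732.8, "Molecular chaperone"),
        ("1125059", 38565.1, "N/A"),
        ("985714", 19689.8, "N/A"),
        ("986569", 18720.1, "N/A"),
        ("907400", 15059.6, "N/A"),
        ("1138063", 12331.1, "N/A"),
        ("1039918", 11506.3, "Molecular chaperone"),
        ("961630", 9712.31, "Histone H4"),
        ("1067414", 9622.65, "N/A"),
        ("1124376", 9300.14, "Histones H3 and H4"),
    ],
    "PDB": [
        ("1067414", 20972.3, "N/A"),
        ("1138063", 18989.4, "N/A"),
        ("1098806", 16159.1, "N/A"),
        ("1125059", 13738.2, "N/A"),
        ("957843", 13582.2, "GAPDH"),
        ("907400", 12134.0, "N/A"),
        ("1124376", 10231.8, "Histones H3 and H4"),
        ("1103054", 9425.23, "N/A"),
        ("961630", 9060.03, "Histone H4"),
        ("981017", 6404.74, "N/A"),
    ],
    "MPY": [
        ("957843", 19500.8, "GAPDH"),
        ("892438", 18481.5, "N/A"),
        ("1067414", 13726.7, "N/A"),
        ("1098806", 11293.0, "N/A"),
        ("987363", 10269.6, "N/A"),
        ("1138063", 9857.26, "N/A"),
        ("1041746", 9720.97, "N/A"),
        ("1124376", 8576.88, "Histones H3 and H4"),
        ("1127611", 8393.75, "N/A"),
        ("907400", 8022.94, "N/A"),
    ],
}

#: Per-sample sequencing summary: total reads, expressed genes, KOG-annotated genes.
TRANSCRIPTOME_SUMMARY: dict[str, dict[str, int]] = {
    "WPG": {"total_reads": 116_376_579, "genes_expressed": 10_870, "genes_kog": 4_645},
    "WPGY": {"total_reads": 125_457_058, "genes_expressed": 10_941, "genes_kog": 4_642},
    "MPY": {"total_reads": 47_969_567, "genes_expressed": 10_442, "genes_kog": 4_582},
    "PDB": {"total_reads": 157_335_190, "genes_expressed": 10_599, "genes_kog": 4_621},
}

#: Reference genome catalog: predicted genes and KOG-annotated genes.
GENOME_GENE_COUNT = 12_346
GENOME_KOG_ANNOTATED = 5_686

#: Secondary-metabolite biosynthetic clusters and their member protein IDs.
SECONDARY_CLUSTERS: dict[str, tuple[str, tuple[str, ...]]] = {
    "nrps_1": ("non-ribosomal peptide synthetase cluster", ("1077522", "1099828", "1122331")),
    "pks_1": ("type I polyketide synthase cluster", ("962914",)),
    "nrps_like_1": ("NRPS-like cluster", ("1126844",)),
    "nrps_like_2": ("NRPS-like cluster with PKS domains", ("966209", "1119995")),
    "nrps_like_3": ("NRPS-like cluster", ("1032817",)),
    "pks_like_1": ("PKS-like cluster", ("1116892",)),
    "pks_like_2": ("PKS-like cluster", ("1121687", "970716", "1076327", "970641")),
}

#: Published member protein IDs of the glycolysis panel (the rest of the 43
#: gene models were not listed individually).
GLYCOLYSIS_KNOWN_MEMBERS = (
    "957843",  # GAPDH NAD-binding domain
    "1079835",  # GAPDH catalytic domain
    "1133725",  # class V alcohol dehydrogenase
    "1092436",  # phosphofructokinase
    "1077976",  # phosphoglycerate kinase
)


def top10_matrix(sample_id: str) -> ExpressionMatrix:
    """The top-10 table of one sample as a partial per-million matrix."""
    if sample_id not in TOP10_GENES:
        raise KeyError(f"unknown sample {sample_id!r}; have {sorted(TOP10_GENES)}")
    rows = TOP10_GENES[sample_id]
    df = pd.DataFrame(
        {sample_id: [value for _, value, _ in rows]},
        index=pd.Index([gene for gene, _, _ in rows], name="gene_id"),
    )
    return ExpressionMatrix(df, unit=PER_MILLION, partial=True)


def top10_matrices() -> dict[str, ExpressionMatrix]:
    return {sample: top10_matrix(sample) for sample in TOP10_GENES}


def top10_functions() -> dict[str, str]:
    """Gene ID → function label across all four top-10 tables."""
    out: dict[str, str] = {}
    for rows in TOP10_GENES.values():
        for gene, _, function in rows:
            out.setdefault(gene, function)
    return out


def _placeholders(prefix: str, count: int, start: int = 1) -> list[str]:
    return [f"{prefix}_synthetic_{i:02d}" for i in range(start, start + count)]


def reference_gene_sets() -> GeneSetCollection:
    """Gene-set collection at the published cardinalities.

    Secondary-metabolite clusters carry the published protein IDs; the
    central-metabolism and aroma panels combine the few published member IDs
    with synthetic placeholder IDs to reach the published sizes (43, 25, 11,
    3, 92).  Two synthetic succinate dehydrogenase genes are shared between
    the TCA and ETC sets, and the class V alcohol dehydrogenase (1133725)
    belongs to both glycolysis and aroma, reproducing the published overlap
    structure.
    """
    sdh_shared = _placeholders("sdh", 2)
    definition: dict[str, tuple[str, list[str]]] = {
        "glycolysis": (
            "glycolysis and alcohol dehydrogenase gene models (43)",
            list(GLYCOLYSIS_KNOWN_MEMBERS) + _placeholders("glycolysis", 38),
        ),
        "tca": (
            "tricarboxylic acid cycle genes (25)",
            sdh_shared + _placeholders("tca", 23),
        ),
        "etc": (
            "electron transport chain genes (11; SDH shared with tca)",
            sdh_shared + _placeholders("etc", 9),
        ),
        "glyoxylate": (
            "glyoxylate cycle: two isocitrate lyases and one malate synthase",
            _placeholders("isocitrate_lyase", 2) + _placeholders("malate_synthase", 1),
        ),
        "aroma": (
            "volatile-compound (aroma) related genes (92)",
            ["1133725"] + _placeholders("aroma", 91),
        ),
    }
    for name, (description, members) in SECONDARY_CLUSTERS.items():
        definition[name] = (description, list(members))
    definition["secondary_clusters"] = (
        "all NRPS/PKS cluster genes pooled (13 proteins across 7 clusters)",
        [g for _, members in SECONDARY_CLUSTERS.values() for g in members],
    )
    return make_gene_sets(definition)
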