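"""Feature schema: the 121 named attributes of the ALS phenotype study.

The feature vector concatenates, in fixed order:

* 59 graph-theory metrics of the whole-brain white-matter connectome,
  one block per diffusion weighting (AD, FA, MD, RD).  The printed AD
  block has no ``Mean_degree_AD`` entry (14 metrics instead of the 15
  of the other weightings); the schema reproduces that layout verbatim
  and exposes ``graph_feature_names(include_mean_degree_ad=True)`` for
  the completed 60-entry variant.
* 32 DTI metrics sampled along the corticospinal tract (4 metrics x
  2 hemispheres x 4 rostrocaudal ROI levels).
* 18 fractal-dimension values (general structure / surface / skeleton,
  WM and GM, left / right / whole brain) plus 2 brain-parenchymal
  fractions.
* 2 demographic and 8 clinical attributes.

Block tags allow slicing the table into the 101 WM, 10 GM and 10
demographic/clinical attribute groups used in the study design.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Order of the five diagnostic classes and their integer coding.
PHENOTYPE_NAMES = ("Control", "ALS-CST+", "ALS-CST-", "ALS-Cl", "ALS-FTD")
PHENOTYPE_CODES = {name: code for code, name in enumerate(PHENOTYPE_NAMES)}

#: Default cohort composition (subjects per phenotype).
DEFAULT_GROUP_SIZES = {
    "Control": 15,
    "ALS-CST+": 21,
    "ALS-CST-": 26,
    "ALS-Cl": 23,
    "ALS-FTD": 21,
}

GRAPH_WEIGHTINGS = ("AD", "FA", "MD", "RD")

#: The 14 graph metrics shared by every weighting, in table order.
GRAPH_METRICS_COMMON = (
    "Assortativity",
    "Density",
    "Mean_clustering_coefficient",
    "Transitivity",
    "Global_efficiency",
    "Mean_local_efficiency",
    "Modularity",
    "Modularity_Louvian",
    "Characteristic_path_length",
    "Mean_nodal_betweenness",
    "Mean_edge_betweenness",
    "Normalized path length",
    "Normalized clustering",
    "Small world index",
)

CST_METRICS = ("FA", "AD", "RD", "MD")
CST_HEMISPHERES = ("Right", "Left")
CST_LEVELS = ("CP", "PLIC", "CSoLV", "subPMC")

FD_REPRESENTATIONS = ("Gen", "surf", "skel")
FD_HEMIS = ("L", "R", "W")

DEMOGRAPHIC_NAMES = ("Age", "Gender")
CLINICAL_NAMES = (
    "El_Escorial",
    "Dur_Symp",
    "ALSFRS-R",
    "Bulbar",
    "Cervical",
    "Lumbosacral",
    "Resp",
    "Prog_Rate",
)

ALSFRS_SUBSCORES = ("Bulbar", "Cervical", "Lumbosacral", "Resp")


def graph_feature_names(include_mean_degree_ad: bool = False) -> list[str]:
    """Names of the connectome graph metrics in table order.

    The printed table lists ``Mean_degree`` for FA/MD/RD but not for AD
    (59 entries); pass ``include_mean_degree_ad=True`` to append the
    missing entry as a 60th feature.
    """
    names: list[str] = []
    for w in GRAPH_WEIGHTINGS:
        if w != "AD":
            names.append(f"Mean_degree_{w}")
        elif include_mean_degree_ad:
            names.append("Mean_degree_AD")
        names.extend(f"{m}_{w}" for m in GRAPH_METRICS_COMMON)
    return names


def cst_feature_names() -> list[str]:
    """The 32 CST ROI names, metric-major then hemisphere then level."""
    return [
        f"{m}_{h}_{lvl}"
        for m in CST_METRICS
        for h in CST_HEMISPHERES
        for lvl in CST_LEVELS
    ]


def fd_feature_names(tissue: str) -> list[str]:
    """The 9 fractal-dimension names for one tissue ('WM' or 'GM')."""
    if tissue not in ("WM", "GM"):
        raise ValueError(f"unknown tissue {tissue!r}")
    return [
        f"FD_{tissue}_{rep}_{h}" for rep in FD_REPRESENTATIONS for h in FD_HEMIS
    ]


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    block: str  # graph-WM | CST-WM | FD-WM | FD-GM | BPF | demographic | clinical
    category: str  # wm | gm | clinical_demographic


def build_schema(include_mean_degree_ad: bool = False) -> list[SchemaEntry]:
    entries: list[SchemaEntry] = []
    for n in graph_feature_names(include_mean_degree_ad):
        entries.append(SchemaEntry(n, "graph-WM", "wm"))
    for n in cst_feature_names():
        entries.append(SchemaEntry(n, "CST-WM", "wm"))
    for n in fd_feature_names("WM"):
        entries.append(SchemaEntry(n, "FD-WM", "wm"))
    for n in fd_feature_names("GM"):
        entries.append(SchemaEntry(n, "FD-GM", "gm"))
    # BPF columns count toward the WM and GM attribute groups respectively.
    entries.append(SchemaEntry("BPF_WM", "BPF", "wm"))
    entries.append(SchemaEntry("BPF_GM", "BPF", "gm"))
    for n in DEMOGRAPHIC_NAMES:
        entries.append(SchemaEntry(n, "demographic", "clinical_demographic"))
    for n in CLINICAL_NAMES:
        entries.append(SchemaEntry(n, "clinical", "clinical_demographic"))
    return entries


SCHEMA: list[SchemaEntry] = build_schema()
FEATURE_NAMES: list[str] = [e.name for e in SCHEMA]

WM_FEATURES = [e.name for e in SCHEMA if e.category == "wm"]
GM_FEATURES = [e.name for e in SCHEMA if e.category == "gm"]
CLINICAL_DEMOGRAPHIC_FEATURES = [
    e.name for e in SCHEMA if e.category == "clinical_demographic"
]

# Published feature-selection fixtures: the attribute subsets reported for
# (a) the five-class task, (b) controls / ALS-CST+ / ALS-CST-, and
# (c) controls / ALS-Cl / ALS-FTD.  Transcribed verbatim up to obvious
# typographical normalization of the printed names.
TABLE2_SELECTION = [
    "Assortativity_AD",
    "Global_efficiency_FA",
    "Mean_local_efficiency_FA",
    "Mean_edge_betweenness_FA",
    "Normalized path length_MD",
    "Assortativity_RD",
    "Density_RD",
    "Mean_local_efficiency_RD",
    "Normalized path length_RD",
    "FA_Right_CP",
    "FA_Right_subPMC",
    "AD_Right_CP",
    "AD_Right_PLIC",
    "AD_Right_CSoLV",
    "AD_Left_CP",
    "AD_Left_subPMC",
    "RD_Right_CP",
    "RD_Right_PLIC",
    "RD_Right_CSoLV",
    "RD_Right_subPMC",
    "RD_Left_CP",
    "MD_Right_CSoLV",
    "MD_Left_CSoLV",
    "FD_WM_Gen_W",
    "FD_WM_skel_L",
    "FD_WM_skel_R",
    "FD_WM_skel_W",
    "FD_GM_Gen_L",
    "FD_GM_Gen_R",
    "FD_GM_Gen_W",
    "FD_GM_skel_R",
    "FD_GM_skel_W",
    "Gender",
    "El_Escorial",
    "Dur_Symp",
    "Bulbar",
    "Prog_Rate",
]

TABLE3_SELECTION = [
    "Assortativity_AD",
    "Transitivity_FA",
    "Characteristic_path_length_FA",
    "Mean_degree_MD",
    "Normalized clustering_MD",
    "Normalized path length_RD",
    "FA_Right_CP",
    "AD_Right_CP",
    "AD_Right_CSoLV",
    "RD_Right_CP",
    "RD_Right_PLIC",
    "RD_Right_CSoLV",
    "RD_Right_subPMC",
    "MD_Right_CP",
    "MD_Left_CP",
    "Gender",
    "El_Escorial",
    "Dur_Symp",
    "Bulbar",
    "Lumbosacral",
]

TABLE4_SELECTION = [
    "Density_AD",
    "Mean_local_efficiency_AD",
    "Mean_edge_betweenness_AD",
    "Density_MD",
    "Mean_clustering_coefficient_MD",
    "Mean_local_efficiency_MD",
    "Normalized path length_RD",
    "FA_Left_PLIC",
    "FA_Left_CSoLV",
    "FA_Left_subPMC",
    "AD_Right_CP",
    "AD_Right_PLIC",
    "RD_Right_CP",
    "RD_Right_PLIC",
    "RD_Right_CSoLV",
    "RD_Right_subPMC",
    "MD_Right_CP",
    "MD_Left_CP",
    "MD_Left_subPMC",
    "FD_WM_skel_W",
    "FD_GM_Gen_R",
    "FD_GM_skel_L",
    "FD_GM_skel_R",
    "FD_GM_skel_W",
    "El_Escorial",
    "Dur_Symp",
    "ALSFRS-R",
]

WEKA_SELECTIONS = {
    "table2": TABLE2_SELECTION,
    "table3": TABLE3_SELECTION,
    "table4": TABLE4_SELECTION,
}
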