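"""Bundled reference tables.

Three small tables ship with the package:

* ``serum_biomarkers.tsv`` — the reported serum biomarker panel: metabolite
  names, their 1H chemical shifts/multiplicities, and the direction of change
  for the two contrasts (disease model vs. control, treated vs. model).
* ``biomarker_annotations.tsv`` — database annotations (HMDB / KEGG compound
  ids) for the query metabolites used in pathway analysis.
* ``pathway_analysis_metpa.tsv`` — a MetPA-style pathway-analysis result table
  (hits, totals, raw p, -log(p), topology impact) used as a reference input.

A fourth file, ``syspharm_pathways_synthetic.txt``, is a synthetic stand-in
for a systems-pharmacology pathway list (the original database export is not
redistributable); it is a list of 234 KEGG-style pathway names carrying the
documented overlap structure.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_biomarker_panel",
    "load_biomarker_annotations",
    "load_pathway_analysis",
    "load_syspharm_pathways",
    "build_enrichment_query",
    "LIPID_CLASS_ENTRIES",
]

#: Panel entries excluded from compound-id based pathway analysis: lipid and
#: macromolecule signals that have no single small-molecule database identity.
LIPID_CLASS_ENTRIES = frozenset(
    {"HDL", "Lipids", "N-Acetyl glycoprotein", "LDL", "VLDL"}
)

#: Composite resonances resolved into their constituent metabolites before
#: annotation (overlapping singlets that cannot be separated at 500 MHz).
COMPOSITE_ENTRIES = {"TMAO/Betaine": ("TMAO", "Betaine")}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("sysmetab.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_biomarker_panel() -> pd.DataFrame:
    """Serum biomarker panel with per-contrast direction annotations."""
    return _read("serum_biomarkers.tsv")


def load_biomarker_annotations() -> pd.DataFrame:
    """HMDB/KEGG annotations for the enrichment query metabolites."""
    return _read("biomarker_annotations.tsv")


def load_pathway_analysis() -> pd.DataFrame:
    """Reference MetPA-style pathway analysis table."""
    return _read("pathway_analysis_metpa.tsv")


def load_syspharm_pathways() -> list[str]:
    """Synthetic stand-in list of systems-pharmacology pathway names."""
    ref = resources.files("sysmetab.data").joinpath(
        "syspharm_pathways_synthetic.txt"
    )
    with ref.open("r") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def build_enrichment_query(
    panel: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Derive the pathway-analysis query from the biomarker panel.

    Lipid-class and glycoprotein entries are dropped (no compound identity),
    and composite resonances are split into their constituent metabolites.
    The result is joined against the annotation table to attach KEGG ids.

    Returns a DataFrame with columns ``query`` and ``kegg``.
    """
    if panel is None:
        panel = load_biomarker_panel()
    if annotations is None:
        annotations = load_biomarker_annotations()
    names: list[str] = []
    for name in panel["metabolite"]:
        if name in LIPID_CLASS_ENTRIES:
            continue
        names.extend(COMPOSITE_ENTRIES.get(name, (name,)))
    ann = annotations.set_index(annotations["query"].str.casefold())
    rows = []
    for name in names:
        key = name.casefold()
        if key in ann.index:
            rows.append({"query": ann.loc[key, "query"], "kegg": ann.loc[key, "kegg"]})
        else:
            rows.append({"query": name, "kegg": None})
    return pd.DataFrame(rows)
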