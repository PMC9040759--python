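"""Packaged gene-family -> N-cycle pathway map (69 families).

Covers the 68 NCycDB gene families plus nifB, each assigned to exactly one
of the nine pathways; ammonia-monooxygenase subunits carry archaeal vs
bacterial domain tags so the amoA archaea:bacteria ratio can be computed.
Users with their own curation can load a TSV via
:meth:`ncycomm.tables.GeneFamilyMap.from_tsv` instead.
"""

from __future__ import annotations

from .tables import GeneFamilyMap

_PATHWAY_FAMILIES: dict[str, list[str]] = {
    "nitrification": [
        "amoA_A", "amoB_A", "amoC_A",  # archaeal ammonia monooxygenase
        "amoA_B", "amoB_B", "amoC_B",  # bacterial ammonia monooxygenase
        "hao",                          # hydroxylamine oxidoreductase
        "nxrA", "nxrB",                 # nitrite oxidoreductase
    ],
    "denitrification": [
        "nirK", "nirS",                 # nitrite -> nitric oxide
        "norB", "norC", "norZ",         # nitric oxide -> nitrous oxide
        "nosZ",                         # nitrous oxide -> dinitrogen
    ],
    "DNRN": [  # dissimilatory nitrate reduction to nitrite
        "narG", "narH", "narI", "napA", "napB",
    ],
    "DNRA": [  # dissimilatory nitrite reduction to ammonia
        "nirB", "nirD", "nrfA", "nrfB", "nrfC", "nrfD",
    ],
    "ANRN": [  # assimilatory nitrate reduction to nitrite
        "nasA", "nasB", "narB", "NR",
    ],
    "ANRA": [  # assimilatory nitrite reduction to ammonia
        "nirA", "nit-6",
    ],
    "nitrogen fixation": [
        "nifH", "nifD", "nifK", "nifW", "nifB", "anfG", "vnfG",
    ],
    "anammox": [
        "hzsA", "hzsB", "hzsC",         # hydrazine synthase
        "hdh",                          # hydrazine dehydrogenase
        "hzo",                          # hydrazine oxidoreductase
    ],
    "ammonification": [  # organic-N decomposition and synthesis
        "ureA", "ureB", "ureC",
        "gdh_K00260", "gdh_K00261", "gdh_K00262", "gdh_K15371",
        "glnA", "glsA", "asnB", "ansB", "gltB", "gltD",
        "nao", "nmo", "cynS", "nthA", "nthB", "nit", "amiE",
        "ald", "dch", "hyuA", "gudB", "pip",
    ],
}

_DOMAIN_TAGS: dict[str, str] = {
    "amoA_A": "archaeal",
    "amoB_A": "archaeal",
    "amoC_A": "archaeal",
    "amoA_B": "bacterial",
    "amoB_B": "bacterial",
    "amoC_B": "bacterial",
}

#: amoA variants used for the archaea:bacteria ammonia-oxidation ratio.
AMOA_FAMILIES = ("amoA_A", "amoA_B")


def default_gene_family_map() -> GeneFamilyMap:
    """The packaged 69-family map as a :class:`GeneFamilyMap`."""
    pathway = {
        fam: pw for pw, fams in _PATHWAY_FAMILIES.items() for fam in fams
    }
    return GeneFamilyMap(pathway=pathway, domain=dict(_DOMAIN_TAGS))
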