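"""Bundled worked-example data from a regional medicinal-plant survey.

A survey of 101 wild medicinal plant species (109 vouchers, 83 genera, 36
families) in the Tianshan wild fruit forest provides a compact real-world
example for the AHP ranking machinery: the 23 species its composite scores
placed in priority class 1, and the survey-level tallies (IUCN red-list
categories and growth forms). Only these published summary rows are
bundled; the underlying specimens and sequences are not public.
"""

from __future__ import annotations

import pandas as pd

#: (species, red-list category, family, composite AHP score, locally endemic, growth form)
CLASS1_PRIORITY_ROWS: list[tuple[str, str, str, float, str, str]] = [
    ("Gagea serotina", "-", "Liliaceae", 0.60, "N", "Perennial Herb"),
    ("Primula algida", "LC", "Primulaceae", 0.60, "Y", "Perennial Herb"),
    ("Leonurus turkestanicus", "LC", "Lamiaceae", 0.60, "Y", "Perennial Herb"),
    ("Lathyrus tuberosus", "LC", "Fabaceae", 0.60, "Y", "Perennial Herb"),
    ("Inula racemosa", "LC", "Asteraceae", 0.60, "Y", "Perennial Herb"),
    ("Ligularia heterophylla", "LC", "Asteraceae", 0.60, "Y", "Perennial Herb"),
    ("Rheum wittrockii", "LC", "Polygonaceae", 0.60, "Y", "Perennial Herb"),
    ("Aquilegia atrovinosa", "LC", "Ranunculaceae", 0.60, "Y", "Perennial Herb"),
    ("Cynoglossum officinale", "-", "Boraginaceae", 0.60, "Y", "Biennial Herb"),
    ("Doronicum altaicum", "LC", "Asteraceae", 0.60, "Y", "Perennial Herb"),
    ("Arctium tomentosum", "LC", "Asteraceae", 0.60, "Y", "Biennial Herb"),
    ("Conium maculatum", "LC", "Apiaceae", 0.61, "Y", "Biennial Herb"),
    ("Oxytropis ochroleuca", "LC", "Fabaceae", 0.61, "Y", "Perennial Herb"),
    ("Roemeria refracta", "LC", "Papaveraceae", 0.61, "Y", "Annual herb"),
    ("Thymus marschallianus", "LC", "Lamiaceae", 0.61, "Y", "Semishrubs"),
    ("Thymus proximus", "LC", "Lamiaceae", 0.61, "Y", "Perennial Semishrubs"),
    ("Rosa laxa", "LC", "Rosaceae", 0.62, "Y", "Shrubs"),
    ("Prunus armeniaca", "NT", "Rosaceae", 0.63, "N", "Deciduous Tree"),
    ("Betula tianschanica", "LC", "Betulaceae", 0.63, "N", "Perennial Tree"),
    ("Glycyrrhiza uralensis", "NT", "Fabaceae", 0.65, "N", "Perennial Herb"),
    ("Rhodiola quadrifida", "NT", "Crassulaceae", 0.65, "N", "Perennial Herb"),
    ("Pseudolysimachion alatavicum", "NT", "Plantaginaceae", 0.69, "Y", "Perennial Herb"),
    ("Aconitum nemorum", "NT", "Ranunculaceae", 0.69, "Y", "Perennial Herb"),
]

#: IUCN red-list tally over the 101 surveyed species (NII = not in the list).
IUCN_TALLY = {"EN": 1, "NT": 5, "DD": 2, "LC": 81, "NII": 12}

#: Growth-form tally over the 101 surveyed species.
GROWTH_FORM_TALLY = {"herb": 81, "shrub": 12, "vine": 2, "tree": 6}

SURVEY_N_SPECIES = 101
SURVEY_N_VOUCHERS = 109
SURVEY_N_GENERA = 83
SURVEY_N_FAMILIES = 36


def class1_priority_table() -> pd.DataFrame:
    """The 23 class-1 species with their composite AHP scores."""
    return pd.DataFrame(
        CLASS1_PRIORITY_ROWS,
        columns=["species", "red_list", "family", "score", "endemic_local", "growth_form"],
    )
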