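"""Bundled reference data.

``reference_cohort`` is the published summary table of a 25-subject
whole-genome sequencing cohort: 15 Mexican-American (MA) women (10 major
depression cases, 5 controls) and 10 Australians of European ancestry
(AU; 5 cases, 5 controls), with sex, age, and total SNV count per
subject.  It drives the descriptive-statistics layer (group burden means,
the Welch test between population burdens, age-balance summaries); the
underlying per-variant data are not public, so the clustering layer is
exercised on synthetic cohorts instead (see :mod:`snvclust.synthetic_cohort`).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .variant_io import CohortManifest


def reference_cohort() -> pd.DataFrame:
    """The bundled cohort summary table.

    Columns: id, group (case/control), population (MA/AU), sex, age,
    total_snvs.
    """
    with resources.files("snvclust.data").joinpath(
        "reference_cohort.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_manifest() -> CohortManifest:
    """The bundled cohort as a :class:`CohortManifest` (metadata columns only)."""
    df = reference_cohort()
    return CohortManifest(df[["id", "group", "population", "sex", "age"]].copy())
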