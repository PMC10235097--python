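"""Bundled published summary tables.

Two small tables of published per-chromosome Gibbs entropy estimates
(molar units, J·K⁻¹·mol⁻¹, J-divergence based) ship with the package:

* Arabidopsis thaliana wild-type controls, msh1 memory / non-memory
  progeny (generations 1 and 3) and the met1 CG-hypomethylation mutant;
* human healthy tissues, matched cancers and metastases, and naive
  embryonic stem cell replicates, all against a common blood B-cell
  reference.

They let the information-gain / free-energy machinery be exercised on
real published numbers without any sequencing download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("methylthermo").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_arabidopsis_entropies() -> pd.DataFrame:
    """Arabidopsis per-chromosome Gibbs entropies (J·K⁻¹·mol⁻¹).

    Columns: sample, group, control_group, chromosome, entropy.
    """
    df = _load("arabidopsis_chromosome_entropy.tsv")
    df["control_group"] = df["control_group"].fillna("")
    return df


def load_human_entropies() -> pd.DataFrame:
    """Human tissue per-chromosome Gibbs entropies (J·K⁻¹·mol⁻¹).

    Columns: tissue, chromosome, entropy.
    """
    return _load("human_tissue_chromosome_entropy.tsv")
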