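"""Packaged synthetic stand-ins for the curated supplementary tables.

The real curated tables (the 340-structure human set, the 70-structure /
52-species set, and the FA ligand exclusion list) are supplementary files
of the original study and are not redistributed here.  The packaged files
are *synthetic* stand-ins generated by
:func:`fapocket.synthetic.make_training_table` and
:func:`fapocket.synthetic.write_ligand_exclusion_list`; they reproduce the
real tables' shape (row counts, species counts, column layout) so loaders
and pipelines can be exercised offline.  Point the loaders at the real
files to work with the published curation.
"""

from importlib import resources
from pathlib import Path

_FILES = {
    "human": "FA_MannuallyCurated_Train.synthetic.tsv",
    "all_species": "FA_AllSpecie_Train.synthetic.tsv",
    "ligand_exclusion": "LigandTableFA.synthetic.txt",
}


def table_path(kind: str) -> Path:
    """Path to a packaged synthetic table: 'human', 'all_species', or
    'ligand_exclusion'."""
    if kind not in _FILES:
        raise KeyError(f"unknown table kind {kind!r}; options: {sorted(_FILES)}")
    return Path(resources.files(__package__) / _FILES[kind])
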