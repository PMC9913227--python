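"""Packaged reference data: the published annotations of the two snake-eel
mitogenomes (GenBank OM421636, *Ophichthus evermanni*, 17,759 bp; OP154196,
*O. erabo*, 17,856 bp) transcribed from their feature tables, and the
published per-region composition/skew table. These carry coordinates and
printed percentages only — no genome sequence is distributed."""

from __future__ import annotations

from importlib import resources

from .annotation import Annotation, parse_feature_table

_DATA = resources.files(__package__) / "data"


def _load(name: str) -> Annotation:
    return parse_feature_table((_DATA / name).read_text())


def load_evermanni() -> Annotation:
    """Annotation of the *Ophichthus evermanni* mitogenome (OM421636)."""
    return _load("ophichthus_evermanni_features.tsv")


def load_erabo() -> Annotation:
    """Annotation of the *Ophichthus erabo* mitogenome (OP154196)."""
    return _load("ophichthus_erabo_features.tsv")


def load_composition_table():
    """Published per-region composition percentages and skews as a DataFrame."""
    import pandas as pd

    with resources.as_file(_DATA / "mitogenome_composition.tsv") as path:
        return pd.read_csv(path, sep="\t", comment="#")


__all__ = ["load_composition_table", "load_erabo", "load_evermanni"]
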