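"""Bundled published data: screen frequency tables and the external prion scale.

The two frequency tables carry the per-residue frequencies printed for the
hnRNPA1- and hnRNPA2-fusion screens (selected vs naive libraries for the
degradation and prion comparisons), along with the published ln(OR) and
p-value columns for cross-checking. The external prion-propensity
reference scale is third-party input data (see the JSON file's citation),
used only for cross-scale comparison.
"""

from __future__ import annotations

import json
from importlib.resources import files

import pandas as pd

from .propensity import AminoAcidScale, table_from_frequencies
from .seqcore import CANONICAL_GROUPS

_DATA = files("prldscreen.data")

_KIND_FILES = {
    "degradation": "degradation_library_frequencies.tsv",
    "prion": "prion_library_frequencies.tsv",
}


def load_published_frequencies(kind: str) -> pd.DataFrame:
    """Tidy frequency table for one comparison kind (degradation | prion).

    Columns: context (A1 | A2), residue (one-letter code or group name),
    is_group, f_sel, f_ref, ln_or_printed, p_printed.
    """
    try:
        fname = _KIND_FILES[kind]
    except KeyError:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(_KIND_FILES)}") from None
    with (_DATA / fname).open() as handle:
        df = pd.read_csv(handle, sep="\t", comment="#")
    df["is_group"] = df["is_group"].astype(bool)
    return df


def published_table(kind: str, context: str) -> pd.DataFrame:
    """Regenerate a propensity table from the published frequencies.

    Applies the odds-ratio/log formulas to the printed 3-decimal
    frequencies for one library pair; group rows use the printed group
    frequencies (which pool member counts before rounding).
    """
    df = load_published_frequencies(kind)
    slice_ = df.loc[df["context"] == context]
    if slice_.empty:
        raise ValueError(f"unknown context {context!r} for kind {kind!r}")
    residues = slice_.loc[~slice_["is_group"]]
    groups = slice_.loc[slice_["is_group"]]
    return table_from_frequencies(
        f_sel=dict(zip(residues["residue"], residues["f_sel"])),
        f_ref=dict(zip(residues["residue"], residues["f_ref"])),
        groups=CANONICAL_GROUPS,
        group_frequencies=(
            dict(zip(groups["residue"], groups["f_sel"])),
            dict(zip(groups["residue"], groups["f_ref"])),
        ),
        scale_kind=kind,
        context=context,
    )


def published_scale(name: str) -> AminoAcidScale:
    """A bundled scale by name: {a1,a2}_{degradation,prion} or papa_prion.

    The four screen-derived scales carry the published ln(OR) values (not
    recomputed ones, so they match the printed tables to 2 decimals); the
    external papa_prion scale is the bundled third-party reference.
    """
    if name == "papa_prion":
        return papa_scale()
    try:
        context, kind = name.split("_", 1)
        context = context.upper()
        df = load_published_frequencies(kind)
    except ValueError:
        raise ValueError(
            f"unknown scale {name!r}; expected a1_degradation, a2_degradation, "
            "a1_prion, a2_prion or papa_prion"
        ) from None
    slice_ = df.loc[(df["context"] == context) & (~df["is_group"])]
    if slice_.empty:
        raise ValueError(f"unknown scale context in {name!r}")
    return AminoAcidScale(
        name=name,
        values=dict(zip(slice_["residue"], slice_["ln_or_printed"])),
        kind=kind,
        context=context,
    )


def papa_scale() -> AminoAcidScale:
    """The external per-residue prion-propensity reference scale."""
    payload = json.loads((_DATA / "papa_prion_propensity.json").read_text())
    return AminoAcidScale(
        name=payload["name"],
        values=payload["values"],
        kind=payload["kind"],
        context=payload["context"],
    )
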