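"""32-state encoding of the abundance census and NEXUS export.

Raw abundances g_ab are log-transformed and scaled by the matrix-wide
maximum g_max, then rounded onto 32 ordered character states:

    state(a, b) = round( ln(g_ab + 1) / ln(g_max + 1) * 31 )

written with the alphanumeric alphabet 0-9, A-V.  The log transform absorbs
unequal genome sizes and right-skewed copy numbers; scaling by the single
matrix-wide maximum keeps states comparable across genomes.  Rounding is
half-up (0.5 rounds to 1) so that state boundaries are stable and documented
rather than subject to banker's rounding.

The same encoded matrix serves two tree orientations: a tree of life (ToL;
taxa = genomes, characters = terms) and a tree of functions (ToF; taxa =
terms, characters = genomes), which are transposes of one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .census import CensusMatrix

N_STATES = 32
SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUV"
_SYMBOL_TO_STATE = {c: i for i, c in enumerate(SYMBOLS)}


def state_symbol(state: int) -> str:
    """Map a state 0..31 to its character: 0-9 then A-V."""
    if int(state) != state or not 0 <= state <= 31:
        raise ValueError(f"state must be an integer in [0, 31], got {state!r}")
    return SYMBOLS[int(state)]


def symbol_state(symbol: str) -> int:
    try:
        return _SYMBOL_TO_STATE[symbol]
    except KeyError:
        raise ValueError(f"unknown state symbol {symbol!r}") from None


def encode_abundance(g: np.ndarray | int, g_max: int) -> np.ndarray | int:
    """Apply the log/max-scaled 32-state transform to raw abundances."""
    if g_max < 1:
        raise ValueError("g_max must be >= 1")
    arr = np.asarray(g)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    ratio = np.log(arr + 1.0) / math.log(g_max + 1.0)
    states = np.floor(ratio * 31.0 + 0.5).astype(int)  # half-up rounding
    states = np.clip(states, 0, 31)
    if np.isscalar(g):
        return int(states)
    return states


@dataclass
class EncodedMatrix:
    """Census encoded into ordered states 0..31 (genomes x terms)."""

    states: pd.DataFrame
    g_max: int
    superkingdom: pd.Series

    @property
    def genomes(self) -> list[str]:
        return list(self.states.index)

    @property
    def terms(self) -> list[str]:
        return list(self.states.columns)

    @property
    def symbols(self) -> pd.DataFrame:
        return self.states.map(lambda s: SYMBOLS[s])

    def to_tsv(self, path_or_stream) -> None:
        self.symbols.to_csv(path_or_stream, sep="\t", index_label="organism_id")


@dataclass
class CharacterMatrixView:
    """A taxa x characters orientation of an encoded matrix.

    ``ToL``: taxa are genomes, characters are terms (evolution of species).
    ``ToF``: taxa are terms, characters are genomes (evolution of functions).
    """

    taxa: list[str]
    characters: list[str]
    states: np.ndarray  # (n_taxa, n_characters) ints in [0, 31]
    orientation: Literal["ToF", "ToL"]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("states shape does not match taxa/characters")
        if self.states.size and (self.states.min() < 0 or self.states.max() > 31):
            raise ValueError("states must lie in [0, 31]")


def encode(census: CensusMatrix) -> EncodedMatrix:
    """Encode a census into the 32-state matrix using its global maximum."""
    g_max = census.g_max
    if g_max < 1:
        raise ValueError("census maximum abundance must be >= 1")
    states = encode_abundance(census.data.to_numpy(), g_max)
    df = pd.DataFrame(states, index=census.data.index,
                      columns=census.data.columns)
    return EncodedMatrix(states=df, g_max=g_max,
                         superkingdom=census.superkingdom.copy())


def orient(encoded: EncodedMatrix, target: Literal["ToF", "ToL"]) -> CharacterMatrixView:
    """Produce the taxa x characters view for a tree of life or of functions."""
    if encoded.states.size == 0:
        raise ValueError("empty encoded matrix")
    if target == "ToL":
        return CharacterMatrixView(taxa=encoded.genomes, characters=encoded.terms,
                                   states=encoded.states.to_numpy(), orientation="ToL")
    if target == "ToF":
        return CharacterMatrixView(taxa=encoded.terms, characters=encoded.genomes,
                                   states=encoded.states.to_numpy().T, orientation="ToF")
    raise ValueError(f"target must be 'ToF' or 'ToL', got {target!r}")


def state_alphabet(g_max: int) -> list[int]:
    """Distinct states reachable by encoding the full sweep 0..g_max.

    The transform is monotone in g, so the reachable set is determined by
    the integer just above each state's lower boundary; this evaluates the
    encoder at those candidates instead of materializing the whole sweep.
    """
    if g_max < 1:
        raise ValueError("g_max must be >= 1")
    log_gmax = math.log(g_max + 1.0)
    candidates = {0, int(g_max)}
    for s in range(N_STATES):
        # smallest g with ratio*31 >= s - 0.5
        lo = math.exp((s - 0.5) / 31.0 * log_gmax) - 1.0
        for g in (math.floor(lo), math.ceil(lo), math.ceil(lo) + 1):
            if 0 <= g <= g_max:
                candidates.add(int(g))
    states = {int(encode_abundance(g, g_max)) for g in candidates}
    return sorted(states)


def _nexus_label(label: str) -> str:
    if any(ch in label for ch in " ()[]{}/\\,;:=*'\"`+<>-"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus(view: CharacterMatrixView,
                polarity: Literal["max", "min"]) -> str:
    """Render a NEXUS matrix with ordered states and ancestral-state polarity.

    ``polarity='max'`` declares V (state 31) ancestral — the rooting used for
    trees of functions, where the most abundant function is taken as the
    oldest.  ``polarity='min'`` declares 0 ancestral — the rooting used for
    trees of life, assuming an ancestral genome of minimal repertoire.  The
    PAUP block carries the corresponding Lundberg rooting directive.
    """
    if polarity not in ("max", "min"):
        raise ValueError("polarity must be 'max' or 'min'")
    if len(set(view.taxa)) != len(view.taxa):
        raise ValueError("duplicate taxon labels")
    anc_symbol = "V" if polarity == "max" else "0"
    ntax, nchar = view.states.shape
    pad = max(len(_nexus_label(t)) for t in view.taxa) + 2
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={ntax} NCHAR={nchar};",
        # the full alphabet is spelled out (PAUP's 0~9A~V range shorthand
        # trips up several NEXUS readers)
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{SYMBOLS}" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for i, taxon in enumerate(view.taxa):
        row = "".join(SYMBOLS[s] for s in view.states[i])
        lines.append(f"        {_nexus_label(taxon):<{pad}}{row}")
    lines += [
        "    ;",
        "END;",
        "",
        "BEGIN ASSUMPTIONS;",
        "    OPTIONS DEFTYPE=ORD;",
        "    TYPESET * default = ord: 1-.;",
        "END;",
        "",
        "BEGIN PAUP;",
        f"    [! Lundberg rooting: ancestral state {anc_symbol} "
        f"({'matrix maximum' if polarity == 'max' else 'matrix minimum'})]",
        f"    ANCSTATES lundberg VECTOR = {anc_symbol * nchar};",
        "    SET ANCSTATES = lundberg;",
        "    ROOT ROOTMETHOD=LUNDBERG;",
        "END;",
        "",
    ]
    return "\n".join(lines)
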