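"""Supported ion species (fully stripped light ions, H through Ne)."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class IonSpecies:
    """A fully ionized light ion, identified by its element symbol.

    The nine supported species form a fixed bijection between symbol,
    atomic number and mass number; arbitrary isotopes are not modelled.
    """

    atomic_number: int
    symbol: str
    mass_number: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbol


_ION_TABLE = [
    IonSpecies(1, "H", 1),
    IonSpecies(2, "He", 4),
    IonSpecies(3, "Li", 7),
    IonSpecies(4, "Be", 9),
    IonSpecies(5, "B", 11),
    IonSpecies(6, "C", 12),
    IonSpecies(7, "N", 14),
    IonSpecies(8, "O", 16),
    IonSpecies(10, "Ne", 20),
]

#: All supported ions in order of increasing atomic number.
IONS: tuple[IonSpecies, ...] = tuple(_ION_TABLE)

ION_BY_SYMBOL: dict[str, IonSpecies] = {ion.symbol: ion for ion in IONS}


def get_ion(symbol: str) -> IonSpecies:
    """Look up an ion by element symbol (case-insensitive).

    Raises
    ------
    KeyError
        If the symbol is not one of the nine supported species.
    """
    key = symbol.strip().capitalize()
    try:
        return ION_BY_SYMBOL[key]
    except KeyError:
        valid = ", ".join(i.symbol for i in IONS)
        raise KeyError(
            f"unknown ion symbol {symbol!r}; supported ions: {valid}"
        ) from None
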