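"""The default enzyme panel.

All recognition sites are palindromic, so a single-strand scan finds every
site once.  Cut offsets follow the standard nomenclature (position of the
cut within the recognition sequence on the top strand).
"""
from .records import Enzyme

PANEL = {
    e.name: e
    for e in (
        Enzyme("DpnII", "GATC", 0),
        Enzyme("EcoRI", "GAATTC", 1),
        Enzyme("HindIII", "AAGCTT", 1),
        Enzyme("NdeI", "CATATG", 2),
        Enzyme("PstI", "CTGCAG", 5, "three_prime"),
        Enzyme("SacI", "GAGCTC", 5, "three_prime"),
        Enzyme("SacII", "CCGCGG", 4, "three_prime"),
        Enzyme("SalI", "GTCGAC", 1),
        Enzyme("XbaI", "TCTAGA", 1),
        Enzyme("XhoI", "CTCGAG", 1),
    )
}

#: Enzyme -> spacing map used by the default redesign plan (bp).
DEFAULT_SPACINGS = {"DpnII": 400, "XbaI": 1500, "HindIII": 2000, "NdeI": 6000}


def get_enzyme(name: str) -> Enzyme:
    try:
        return PANEL[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; known: {sorted(PANEL)}") from None
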