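"""Versioned categorical vocabularies for molecular graph features.

The index tables follow the OGB molecular-graph convention (capped value
lists with a trailing ``"misc"`` bucket) so serialized graphs are stable
across releases.  Order matters: changing these lists is a format change.
"""

VOCAB_VERSION = 1

ATOM_FEATURES = {
    "atomic_num": list(range(1, 119)) + ["misc"],
    "degree": list(range(0, 11)) + ["misc"],
    "formal_charge": list(range(-5, 7)) + ["misc"],
    "hybridization": ["SP", "SP2", "SP3", "SP3D", "SP3D2", "misc"],
    "chirality": ["CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW",
                  "CHI_TETRAHEDRAL_CCW", "CHI_OTHER", "misc"],
    "is_aromatic": [False, True],
    "num_hs": list(range(0, 9)) + ["misc"],
    "total_valence": list(range(0, 13)) + ["misc"],
    "is_in_ring": [False, True],
}

#: fixed atom-attribute order (9 channels)
ATOM_FEATURE_ORDER = ("atomic_num", "degree", "formal_charge", "hybridization",
                      "chirality", "is_aromatic", "num_hs", "total_valence",
                      "is_in_ring")

BOND_FEATURES = {
    "bond_type": ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC", "misc"],
    "is_conjugated": [False, True],
    "stereo": ["STEREONONE", "STEREOZ", "STEREOE",
               "STEREOCIS", "STEREOTRANS", "STEREOANY"],
}

#: fixed bond-attribute order (3 channels)
BOND_FEATURE_ORDER = ("bond_type", "is_conjugated", "stereo")

ATOM_FEATURE_DIMS = tuple(len(ATOM_FEATURES[k]) for k in ATOM_FEATURE_ORDER)
BOND_FEATURE_DIMS = tuple(len(BOND_FEATURES[k]) for k in BOND_FEATURE_ORDER)

#: shortest-path sentinel for disconnected atom pairs
SPD_UNREACHABLE = -1


def safe_index(values: list, value) -> int:
    """Index of ``value`` in the vocabulary, else the trailing misc bucket."""
    try:
        return values.index(value)
    except ValueError:
        return len(values) - 1
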