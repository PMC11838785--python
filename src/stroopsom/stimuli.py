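"""The 16-color stimulus set: RGB semantic vectors and phonetic lexical vectors.

Semantic representations are simply the RGB triples of 16 standard colors
(the CSS/HTML basic color set) on a 0-1 scale, e.g. red = (1, 0, 0).
Lexical representations encode the Spanish color names: each name's broad
IPA transcription is mapped phoneme by phoneme to a short articulatory
feature vector (vowels: height, backness, roundedness; consonants: place,
manner, voicing, each scaled to [0, 1]), concatenated in order and
zero-padded to a fixed number of phoneme slots.  The assembled lexicon's
vectors are rescaled to unit median pairwise distance so the lexical
feature space has the same metric scale as RGB space.  Phonetically
similar words receive nearby vectors, which is what lets the lexical
map organize them topographically.

The exact inventory of color words and their feature vectors used in
earlier lexicon models of this family is unpublished; this module is a
reconstruction at the level of detail the procedure states, so downstream
accuracy and response-time figures are stochastic approximations rather
than exact reproductions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .errors import DataError
from .lateral_som import InputSet

__all__ = [
    "ColorEntry",
    "ColorLexicon",
    "PhonemeFeatureScheme",
    "default_lexicon",
    "default_scheme",
    "encode_word",
    "incongruent_pairs",
]

# Vowel features: (height, backness, roundedness), each in [0, 1].
_VOWELS = {
    "a": (0.0, 0.5, 0.0),
    "e": (0.5, 0.0, 0.0),
    "i": (1.0, 0.0, 0.0),
    "o": (0.5, 1.0, 1.0),
    "u": (1.0, 1.0, 1.0),
}

# Place and manner indices for the Spanish consonant inventory we need,
# scaled to [0, 1] front-to-back and stop-to-liquid.
_PLACE = {"bilabial": 0.0, "labiodental": 0.2, "dental": 0.4,
          "alveolar": 0.6, "palatal": 0.8, "velar": 1.0}
_MANNER = {"plosive": 0.0, "nasal": 0.2, "trill": 0.4,
           "tap": 0.6, "fricative": 0.8, "lateral": 1.0}

_CONSONANTS = {
    "p": ("bilabial", "plosive", 0.0),
    "b": ("bilabial", "plosive", 1.0),
    "t": ("dental", "plosive", 0.0),
    "d": ("dental", "plosive", 1.0),
    "k": ("velar", "plosive", 0.0),
    "ɡ": ("velar", "plosive", 1.0),    # ɡ
    "m": ("bilabial", "nasal", 1.0),
    "n": ("alveolar", "nasal", 1.0),
    "f": ("labiodental", "fricative", 0.0),
    "s": ("alveolar", "fricative", 0.0),
    "x": ("velar", "fricative", 0.0),
    "β": ("bilabial", "fricative", 1.0),  # β
    "ð": ("dental", "fricative", 1.0),    # ð
    "ɣ": ("velar", "fricative", 1.0),     # ɣ
    "ʎ": ("palatal", "lateral", 1.0),     # ʎ
    "l": ("alveolar", "lateral", 1.0),
    "r": ("alveolar", "trill", 1.0),
    "ɾ": ("alveolar", "tap", 1.0),        # ɾ
}

# Ignored when parsing IPA strings (stress marks, separators).
_IGNORED = {"ˈ", "ˌ", " ", ".", "͡"}

# Per-slot layout: [type flag, f1, f2, f3].  The flag separates vowels
# (1.0) from consonants (0.5) from empty padding (0.0) so that a
# zero-featured consonant is still distinguishable from absence.
_VOWEL_FLAG = 1.0
_CONSONANT_FLAG = 0.5


@dataclass(frozen=True)
class PhonemeFeatureScheme:
    """Phoneme-to-feature table plus the word-template geometry."""

    table: dict
    max_phonemes: int
    feature_dim_per_phoneme: int = 4

    @property
    def vector_length(self) -> int:
        return self.max_phonemes * self.feature_dim_per_phoneme


def _build_table() -> dict:
    table = {}
    for ph, feats in _VOWELS.items():
        table[ph] = (_VOWEL_FLAG, *feats)
    for ph, (place, manner, voicing) in _CONSONANTS.items():
        table[ph] = (_CONSONANT_FLAG, _PLACE[place], _MANNER[manner], voicing)
    return table


def default_scheme(max_phonemes: int = 8) -> PhonemeFeatureScheme:
    """The scheme used for the shipped Spanish color lexicon.

    ``max_phonemes`` is sized to the longest color name (8 phonemes, e.g.
    "plateado" /plateaðo/).
    """
    return PhonemeFeatureScheme(table=_build_table(), max_phonemes=max_phonemes)


def encode_word(ipa: str, scheme: PhonemeFeatureScheme) -> np.ndarray:
    """Encode an IPA transcription as a fixed-length feature vector.

    Per-phoneme feature vectors are concatenated in order; unused trailing
    slots are zero.  Deterministic: the same string always encodes to the
    same vector.
    """
    phonemes = [ch for ch in ipa if ch not in _IGNORED]
    if len(phonemes) > scheme.max_phonemes:
        raise DataError(
            f"word {ipa!r} has {len(phonemes)} phonemes; "
            f"scheme allows at most {scheme.max_phonemes}")
    vec = np.zeros(scheme.vector_length)
    for slot, ph in enumerate(phonemes):
        if ph not in scheme.table:
            raise DataError(f"unknown phoneme {ph!r} in {ipa!r}")
        start = slot * scheme.feature_dim_per_phoneme
        vec[start:start + scheme.feature_dim_per_phoneme] = scheme.table[ph]
    return vec


@dataclass(frozen=True)
class ColorEntry:
    english_name: str
    spanish_name: str
    ipa: str
    rgb: tuple
    lexical_vector: np.ndarray


# (english, spanish, broad IPA, rgb) for the 16 CSS/HTML basic colors.
# Spanish forms are standard dictionary words; the palatal glide in
# "cian"/"fucsia" is encoded with the vowel /i/.
_COLOR_TABLE = [
    ("white",   "blanco",   "ˈblanko",        (1.0, 1.0, 1.0)),
    ("silver",  "plateado", "plateˈaðo", (0.75, 0.75, 0.75)),
    ("gray",    "gris",     "ˈɡɾis", (0.5, 0.5, 0.5)),
    ("black",   "negro",    "ˈneɣɾo", (0.0, 0.0, 0.0)),
    ("red",     "rojo",     "ˈroxo",          (1.0, 0.0, 0.0)),
    ("maroon",  "granate",  "ɡɾaˈnate", (0.5, 0.0, 0.0)),
    ("yellow",  "amarillo", "amaˈɾiʎo", (1.0, 1.0, 0.0)),
    ("olive",   "oliva",    "oˈliβa",    (0.5, 0.5, 0.0)),
    ("lime",    "lima",     "ˈlima",          (0.0, 1.0, 0.0)),
    ("green",   "verde",    "ˈbeɾðe", (0.0, 0.5, 0.0)),
    ("aqua",    "cian",     "ˈsian",          (0.0, 1.0, 1.0)),
    ("teal",    "turquesa", "tuɾˈkesa",  (0.0, 0.5, 0.5)),
    ("blue",    "azul",     "aˈsul",          (0.0, 0.0, 1.0)),
    ("navy",    "marino",   "maˈɾino",   (0.0, 0.0, 0.5)),
    ("fuchsia", "fucsia",   "ˈfuksia",        (1.0, 0.0, 1.0)),
    ("purple",  "morado",   "moˈɾaðo", (0.5, 0.0, 0.5)),
]


@dataclass
class ColorLexicon:
    """The color vocabulary with matching semantic and lexical input sets."""

    entries: list = field(default_factory=list)
    semantic_input_set: InputSet = None
    lexical_input_set: InputSet = None
    scheme: PhonemeFeatureScheme = None

    @property
    def labels(self) -> list:
        return [e.english_name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, name: str) -> ColorEntry:
        for e in self.entries:
            if e.english_name == name or e.spanish_name == name:
                return e
        raise DataError(f"color {name!r} not in lexicon")

    def rgb(self, name: str) -> np.ndarray:
        return np.asarray(self.entry(name).rgb, dtype=float)

    def lexical_vector(self, name: str) -> np.ndarray:
        return self.entry(name).lexical_vector

    def to_dict(self) -> dict:
        return {
            "max_phonemes": self.scheme.max_phonemes,
            "lexical_scale": self.lexical_input_set.median_pairwise_distance,
            "entries": [
                {"english": e.english_name, "spanish": e.spanish_name,
                 "ipa": e.ipa, "rgb": list(e.rgb),
                 "lexical_vector": e.lexical_vector.tolist()}
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColorLexicon":
        scheme = default_scheme(d["max_phonemes"])
        entries = [
            ColorEntry(x["english"], x["spanish"], x["ipa"], tuple(x["rgb"]),
                       np.asarray(x["lexical_vector"], dtype=float))
            for x in d["entries"]
        ]
        return _finalize(entries, scheme,
                         d.get("lexical_scale", DEFAULT_LEXICAL_SCALE))


#: Median pairwise Euclidean distance of the lexical vectors after
#: rescaling, in the units where the RGB set's median pairwise distance
#: is 1.  Sets how sharply a word input focuses the lexical map relative
#: to a color input focusing the semantic map.
DEFAULT_LEXICAL_SCALE = 1.0


def _finalize(entries, scheme, lexical_scale=DEFAULT_LEXICAL_SCALE) -> ColorLexicon:
    names = [e.english_name for e in entries]
    if len(set(names)) != len(names):
        raise DataError("color names are not unique")
    for e in entries:
        if not all(0.0 <= v <= 1.0 for v in e.rgb):
            raise DataError(f"rgb out of range for {e.english_name}")
    vectors = np.stack([e.lexical_vector for e in entries])
    # Distinct words must have distinct vectors or the lexical map cannot
    # separate them.
    if len(np.unique(vectors, axis=0)) != len(entries):
        raise DataError("two lexicon words encode to identical vectors")
    # The absolute scale of the raw phonetic features is arbitrary;
    # rescale the word vectors to a fixed median pairwise distance
    # (``lexical_scale``, in units of the RGB set's median distance) so the
    # lexical map's input sharpness is a controlled property of the
    # stimulus set rather than an accident of the feature encoding.
    raw_scale = float(np.median(pdist(vectors)))
    if raw_scale <= 0:
        raise DataError("degenerate lexical vectors")
    vectors = vectors * (lexical_scale / raw_scale)
    entries = [dataclasses.replace(e, lexical_vector=vectors[i])
               for i, e in enumerate(entries)]
    rgbs = np.array([e.rgb for e in entries], dtype=float)
    lexicon = ColorLexicon(
        entries=list(entries),
        semantic_input_set=InputSet(rgbs, names),
        lexical_input_set=InputSet(vectors, names),
        scheme=scheme,
    )
    if lexicon.semantic_input_set.median_pairwise_distance <= 0:
        raise DataError("degenerate semantic input set")
    return lexicon


def default_lexicon(lexical_scale: float = DEFAULT_LEXICAL_SCALE) -> ColorLexicon:
    """The canonical 16-color lexicon (CSS/HTML basic colors, Spanish names).

    ``lexical_scale`` sets the median pairwise distance of the word
    vectors (RGB units); see :data:`DEFAULT_LEXICAL_SCALE`.
    """
    scheme = default_scheme()
    entries = [
        ColorEntry(en, es, ipa, rgb, encode_word(ipa, scheme))
        for en, es, ipa, rgb in _COLOR_TABLE
    ]
    return _finalize(entries, scheme, lexical_scale)


def incongruent_pairs(lexicon: ColorLexicon):
    """All ordered (target color, distractor word) pairs with target !=
    distractor; n*(n-1) pairs for an n-color lexicon (240 for 16)."""
    names = lexicon.labels
    return [(t, d) for t in names for d in names if d != t]
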