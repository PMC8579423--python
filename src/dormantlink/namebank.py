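"""Synthetic identifier universes: names and a postcode/authority lookup.

Everything here is invented. The name banks deliberately contain
apostrophes, hyphens and diacritics so that standardisation is exercised;
the postcode universe is a small synthetic stand-in for the national
look-up table (real postcode files are licensed and out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SURNAMES = [
    "Smith", "Jones", "Taylor", "Brown", "Williams", "Wilson", "Johnson",
    "Davies", "Robinson", "Wright", "Thompson", "Evans", "Walker", "White",
    "Roberts", "Green", "Hall", "Wood", "Jackson", "Clarke", "Patel",
    "Khan", "Lewis", "James", "Phillips", "Mason", "Mitchell", "Rose",
    "Davis", "Rodgers", "Parker", "Price", "Cook", "Shaw", "Bennett",
    "Begum", "Bell", "Cox", "Richards", "Ward", "O'Brien", "O'Connor",
    "O'Neill", "Müller", "García", "Fernández", "Nguyen", "Ahmed", "Ali",
    "Hussain", "Singh", "Kaur", "Murphy", "Kelly", "Byrne", "Ryan",
    "Walsh", "Doyle", "McCarthy", "Gallagher", "Lloyd-Jones", "Smythe-Hart",
    "Baker", "Carter", "Morris", "Hughes", "Edwards", "Hill", "Moore",
    "Clark", "Harrison", "Scott", "Young", "Morgan", "Allen", "King",
    "Watson", "Harris", "Martin", "Lee", "Turner", "Cooper", "Reid",
    "Stewart", "Campbell", "Murray", "Macdonald", "Fraser", "Hamilton",
    "Graham", "Wallace", "Kerr", "Duncan", "Ross", "Boyle", "Quinn",
    "Sharma", "Kapoor", "Chowdhury", "Rahman", "Islam", "Miah", "Uddin",
    "Kowalski", "Nowak", "Silva", "Santos", "Costa", "Rossi", "Ferrari",
    "Dubois", "Lefèvre", "Laurent", "Öztürk", "Yılmaz", "Papadopoulos",
]

FORENAMES_F = [
    "Anna", "Emma", "Sophie", "Chloe", "Megan", "Jessica", "Lauren",
    "Rebecca", "Charlotte", "Hannah", "Amy", "Bethany", "Katie", "Lucy",
    "Georgia", "Abigail", "Eleanor", "Holly", "Shannon", "Molly",
    "Anna-Marie", "Ellie-May", "Zoë", "Chloë", "Aoife", "Niamh",
    "Siobhán", "Aisha", "Fatima", "Zainab", "Priya", "Anika", "Maria",
    "Sofia", "Elena", "Olivia", "Grace", "Alice", "Isabel", "Rachel",
    "Sarah", "Laura", "Kirsty", "Gemma", "Nicola", "Stacey", "Leah",
    "Paige", "Courtney", "Jade",
]

FORENAMES_M = [
    "Jack", "Daniel", "Thomas", "James", "Joshua", "Matthew", "Ryan",
    "Joseph", "Samuel", "Liam", "Jordan", "Adam", "Michael", "Alexander",
    "Christopher", "Benjamin", "Connor", "Callum", "Jake", "Luke",
    "Mohammed", "Muhammad", "Hasan", "Omar", "Yusuf", "Arjun", "Rohan",
    "Seán", "Cian", "Oisín", "Lewis", "Harry", "George", "Oliver",
    "William", "Nathan", "Kieran", "Aaron", "Scott", "Craig", "Ashley",
    "Jamie-Lee", "Billy-Joe", "Dylan", "Cameron", "Bradley", "Brandon",
    "Kyle", "Curtis", "Reece",
]

#: letter pairs used to build synthetic outward codes, one per authority row
_AREA_LETTERS = [
    "AB", "BC", "CD", "DE", "EF", "FG", "GH", "HJ", "JK", "KL",
    "LM", "MN", "NP", "PQ", "QR", "RS", "ST", "TU", "UV", "VW",
    "WX", "XY", "YZ", "ZA", "AC", "BD", "CE", "DF", "EG", "FH",
    "GJ", "HK", "JL", "KM", "LN", "MP", "NQ", "PR", "QS", "RT",
    "SU", "TV", "UW", "VX", "WY", "XZ", "YA", "ZB", "AD", "BE",
]

_GRID_COLS = 10  # authorities sit on a 5 x 10 grid; neighbours = grid adjacency


@dataclass
class PostcodeLookup:
    """Synthetic national postcode look-up.

    Maps every valid postcode to exactly one local authority and carries a
    symmetric neighbouring-authority relation (grid adjacency), which backs
    the ``neighbouring_authority`` agreement level for postcodes.
    """

    postcode_to_authority: dict = field(default_factory=dict)
    neighbours: dict = field(default_factory=dict)

    @property
    def postcodes(self) -> list:
        return list(self.postcode_to_authority)

    def authority(self, postcode: str) -> str | None:
        return self.postcode_to_authority.get(postcode)

    def are_neighbours(self, auth_a: str, auth_b: str) -> bool:
        return auth_b in self.neighbours.get(auth_a, ())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "postcode": pc,
                "authority": auth,
                "neighbours": "|".join(sorted(self.neighbours[auth])),
            }
            for pc, auth in self.postcode_to_authority.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PostcodeLookup":
        lk = cls()
        for row in frame.itertuples(index=False):
            lk.postcode_to_authority[row.postcode] = row.authority
            lk.neighbours.setdefault(row.authority, set()).update(
                x for x in str(row.neighbours).split("|") if x
            )
        return lk


def build_postcode_lookup(
    n_authorities: int = 50, postcodes_per_authority: int = 20
) -> PostcodeLookup:
    """Build the synthetic postcode universe.

    Authorities ``A01..Ann`` are arranged on a grid; two authorities are
    neighbours iff they are grid-adjacent (the relation is symmetric by
    construction). Each authority owns ``postcodes_per_authority`` codes of
    the form ``XX<district> <sector><unit letters>``.
    """
    if n_authorities > len(_AREA_LETTERS):
        raise ValueError("at most %d authorities supported" % len(_AREA_LETTERS))
    lk = PostcodeLookup()
    auths = [f"A{i + 1:02d}" for i in range(n_authorities)]
    for i, auth in enumerate(auths):
        r, c = divmod(i, _GRID_COLS)
        nbrs = set()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            j = rr * _GRID_COLS + cc
            if 0 <= cc < _GRID_COLS and 0 <= j < n_authorities and rr >= 0:
                nbrs.add(auths[j])
        lk.neighbours[auth] = nbrs
        area = _AREA_LETTERS[i]
        for k in range(postcodes_per_authority):
            district = k // 5 + 1
            sector = k % 5 + 1
            unit = chr(ord("A") + (k % 26)) + chr(ord("A") + ((k * 7 + i) % 26))
            lk.postcode_to_authority[f"{area}{district} {sector}{unit}"] = auth
    return lk


def sample_names(rng: np.random.Generator, sex: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Draw (forename, surname) arrays given a 0/1 sex array (1 = male)."""
    n = len(sex)
    surnames = rng.choice(SURNAMES, size=n).astype(object)
    forenames = np.where(
        sex == 1,
        rng.choice(FORENAMES_M, size=n),
        rng.choice(FORENAMES_F, size=n),
    ).astype(object)
    return forenames, surnames
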