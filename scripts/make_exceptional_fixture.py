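"""Regenerate the packaged synthetic Working List fixture.

Builds ``src/cryogap/data/exceptional_list_synthetic.csv``: a deterministic
775-species, 111-family stand-in for the published Working List of
Exceptional Plants (which is distributed separately).  The fixture embeds,
exactly, the published per-family EF tabulation for the 19 zero-literature
families and the published per-family species totals for the largest
exceptional families; remaining families and all epithets are synthetic
pseudo-Latin.  Run from the repository root:

    python scripts/make_exceptional_fixture.py
"""

from __future__ import annotations

import random
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cryogap.corpus_io import (
    EF_CATEGORIES,
    ExceptionalSpeciesRecord,
    packaged_data,
    write_exceptional_list,
)
from cryogap.gap_analysis import EFBreakdownRow
from cryogap.synthetic_data import (
    DEFAULT_EF_WEIGHTS,
    pseudo_latin_names,
    species_records_from_ef_rows,
)

import pandas as pd

SEED = 1528
TARGET_SPECIES = 775
TARGET_FAMILIES = 111

# Genus lists for the zero-literature families (real names where documented).
GENUS_FOR_FAMILY = {
    "Dipterocarpaceae": ["Shorea", "Dipterocarpus", "Hopea", "Vatica", "Dryobalanops"],
    "Rhizophoraceae": ["Bruguiera", "Rhizophora", "Kandelia", "Ceriops"],
    "Pittosporaceae": ["Pittosporum"],
    "Myristicaceae": ["Myristica", "Horsfieldia"],
    "Podocarpaceae": ["Podocarpus", "Dacrydium"],
    "Santalaceae": ["Santalum", "Exocarpos"],
    "Nymphaeaceae": ["Nymphaea", "Victoria"],
    "Cyperaceae": ["Carex", "Cyperus"],
    "Nyctaginaceae": ["Pisonia", "Rockia"],
    "Urticaceae": ["Pipturus", "Touchardia"],
    "Cymodoceaceae": ["Cymodocea", "Halodule"],
    "Lecythidaceae": ["Bertholletia", "Barringtonia"],
    "Dilleniaceae": ["Dillenia", "Hibbertia"],
    "Scrophulariaceae": ["Myoporum"],
    "Calophyllaceae": ["Calophyllum"],
    "Chrysobalanaceae": ["Chrysobalanus", "Parinari"],
    "Elaeocarpaceae": ["Elaeocarpus"],
    "Hydrangeaceae": ["Hydrangea", "Broussaisia"],
    "Zosteraceae": ["Zostera"],
}

# Per-family species totals for the other large exceptional families, with a
# few documented genera each; remaining species get synthetic genera.
OTHER_FAMILIES = {
    "Arecaceae": (37, ["Cocos", "Elaeis", "Pritchardia", "Livistona"]),
    "Rutaceae": (35, ["Melicope", "Citrus", "Zanthoxylum"]),
    "Campanulaceae": (34, ["Cyanea", "Clermontia", "Lobelia"]),
    "Fabaceae": (32, ["Inga", "Astragalus", "Crotalaria", "Vicia", "Vigna"]),
    "Rubiaceae": (32, ["Coprosma", "Coffea", "Psychotria"]),
    "Orchidaceae": (26, ["Dendrobium", "Paphiopedilum", "Vanda"]),
    "Meliaceae": (25, ["Trichilia", "Ekebergia", "Aglaia"]),
    "Fagaceae": (24, ["Quercus", "Castanea", "Lithocarpus"]),
    "Lauraceae": (24, ["Persea", "Litsea", "Ocotea"]),
    "Sapindaceae": (23, ["Aesculus", "Acer", "Litchi"]),
    "Asteraceae": (22, ["Bidens", "Argyroxiphium"]),
    "Primulaceae": (20, ["Lysimachia", "Primula"]),
    "Amaryllidaceae": (18, ["Crinum", "Clivia"]),
    "Moraceae": (18, ["Artocarpus", "Ficus"]),
    "Myrtaceae": (18, ["Syzygium", "Eugenia"]),
    "Apocynaceae": (14, ["Ochrosia", "Rauvolfia"]),
    "Malvaceae": (12, ["Theobroma", "Hibiscadelphus"]),
    "Sapotaceae": (12, ["Pouteria", "Manilkara"]),
    "Poaceae": (11, ["Zizania", "Ischaemum"]),
    "Anacardiaceae": (10, ["Mangifera", "Spondias"]),
    "Araucariaceae": (10, ["Araucaria", "Agathis"]),
    "Gesneriaceae": (10, ["Cyrtandra"]),
    "Clusiaceae": (7, ["Garcinia"]),
    "Ebenaceae": (6, ["Diospyros"]),
    "Caricaceae": (1, ["Carica"]),
    "Euphorbiaceae": (2, ["Hevea"]),
    "Passifloraceae": (1, ["Passiflora"]),
    "Brassicaceae": (2, ["Wasabia", "Lepidium"]),
}

# Species that must appear verbatim (family, species); they are counted
# against their family's total above.
NAMED_SPECIES = [
    ("Caricaceae", "Carica papaya"),
    ("Arecaceae", "Cocos nucifera"),
    ("Rubiaceae", "Coffea arabica"),
    ("Rutaceae", "Citrus sinensis"),
    ("Arecaceae", "Elaeis guineensis"),
    ("Anacardiaceae", "Mangifera indica"),
    ("Malvaceae", "Theobroma cacao"),
    ("Meliaceae", "Trichilia dregeana"),
    ("Moraceae", "Artocarpus heterophyllus"),
    ("Fagaceae", "Castanea sativa"),
    ("Fagaceae", "Quercus robur"),
    ("Ebenaceae", "Diospyros kaki"),
    ("Lauraceae", "Persea americana"),
    ("Rutaceae", "Citrus limon"),
    ("Meliaceae", "Ekebergia capensis"),
    ("Euphorbiaceae", "Hevea brasiliensis"),
    ("Passifloraceae", "Passiflora edulis"),
    ("Brassicaceae", "Wasabia japonica"),
]


def main() -> None:
    rng = random.Random(SEED)
    frame = pd.read_csv(packaged_data("table_ef_breakdown.csv"))
    ef_rows = [
        EFBreakdownRow(r.family, r.total, r.ef1, r.ef2, r.ef3, r.ef4)
        for r in frame.itertuples(index=False)
    ]
    records = species_records_from_ef_rows(ef_rows, GENUS_FOR_FAMILY, seed=SEED)

    def draw_ef() -> tuple[str, ...]:
        return (rng.choices(EF_CATEGORIES, weights=DEFAULT_EF_WEIGHTS, k=1)[0],)

    named_by_family: dict[str, list[str]] = {}
    for family, species in NAMED_SPECIES:
        named_by_family.setdefault(family, []).append(species)

    for family, (total, genera) in OTHER_FAMILIES.items():
        named = named_by_family.get(family, [])
        for species in named:
            records.append(ExceptionalSpeciesRecord(species, family, ("EF2",)))
        remaining = total - len(named)
        epithets = pseudo_latin_names(
            remaining, SEED + sum(ord(c) for c in family), "epithet", taken=genera
        )
        for k in range(remaining):
            genus = genera[k % len(genera)]
            records.append(
                ExceptionalSpeciesRecord(f"{genus} {epithets[k]}", family, draw_ef())
            )

    # pad to the target sizes with small synthetic families
    n_families_so_far = len({r.family for r in records})
    n_pad_families = TARGET_FAMILIES - n_families_so_far
    n_pad_species = TARGET_SPECIES - len(records)
    pad_families = pseudo_latin_names(n_pad_families, SEED + 99, "family")
    base = n_pad_species // n_pad_families
    extra = n_pad_species - base * n_pad_families
    for i, family in enumerate(pad_families):
        count = base + (1 if i < extra else 0)
        genus_stub = pseudo_latin_names(1, SEED + 200 + i, "genus",
                                        taken=pad_families)[0]
        epithets = pseudo_latin_names(count, SEED + 300 + i, "epithet",
                                      taken=[genus_stub])
        for k in range(count):
            records.append(
                ExceptionalSpeciesRecord(
                    f"{genus_stub} {epithets[k]}", family, draw_ef()
                )
            )

    assert len(records) == TARGET_SPECIES, len(records)
    assert len({r.family for r in records}) == TARGET_FAMILIES
    assert len({r.species for r in records}) == TARGET_SPECIES, "species collide"

    out = Path(__file__).resolve().parents[1] / "src/cryogap/data/exceptional_list_synthetic.csv"
    write_exceptional_list(records, out)
    n_genera = len({r.genus for r in records})
    print(f"wrote {out} ({len(records)} species, "
          f"{len({r.family for r in records})} families, {n_genera} genera)")


if __name__ == "__main__":
    main()
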