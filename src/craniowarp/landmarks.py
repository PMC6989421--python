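"""Canonical landmark dictionary.

The packaged schema defines the full naming convention used throughout the
pipeline: 78 skin landmarks, 78 facial-bone landmarks (36 of which carry the
``craniometric`` role used by the shape-size normalisation), 7 static
calvarial constraint landmarks, and the 7 skull-base reference-frame
landmarks (lateral semicircular canals, glenoid fossae, crista galli).

Each surface landmark additionally stores a canonical *unit direction* on
the head sphere; the synthetic generator evaluates its analytic head-shape
function along that direction, so generated landmark positions are exact
functions of the shape parameters with no mesh-snapping error.  The seven
reference landmarks are interior skull-base points and store canonical
coordinates directly (in mm at the reference head scale of 75 mm).

Left/right pairs use ``_r``/``_l`` suffixes and exactly mirrored directions
about the mid-sagittal plane x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

#: head scale (mm) at which canonical coordinates are expressed
REFERENCE_SCALE = 75.0

#: Table-order names of the 7 reference-frame landmarks
REFERENCE_NAMES = (
    "r_lsc_lateral",
    "l_lsc_lateral",
    "r_lsc_posterior",
    "l_lsc_posterior",
    "r_glenoid",
    "l_glenoid",
    "crista_galli",
)

# Canonical skull-base coordinates (mm at REFERENCE_SCALE).  The six
# vestibular/glenoid points span the horizontal plane; the crista galli sits
# on the midline, anterior and slightly superior.
_REFERENCE_CANONICAL = {
    "r_lsc_lateral": (38.0, 0.0, 0.0),
    "l_lsc_lateral": (-38.0, 0.0, 0.0),
    "r_lsc_posterior": (30.0, -16.0, 0.0),
    "l_lsc_posterior": (-30.0, -16.0, 0.0),
    "r_glenoid": (42.0, 14.0, 0.0),
    "l_glenoid": (-42.0, 14.0, 0.0),
    "crista_galli": (0.0, 52.0, 9.0),
}


@dataclass(frozen=True)
class LandmarkSpec:
    name: str
    role: str
    region: str
    surface: str  # "skin" | "bone" | "interior"
    direction: tuple  # unit direction (surface) or canonical mm position (interior)


def _dir(azim_deg: float, elev_deg: float) -> np.ndarray:
    """Unit direction from azimuth (0 = anterior +y, positive toward +x = patient right)
    and elevation above the horizontal plane."""
    a = np.radians(azim_deg)
    e = np.radians(elev_deg)
    return np.array([np.cos(e) * np.sin(a), np.cos(e) * np.cos(a), np.sin(e)])


def _mirror(d: np.ndarray) -> np.ndarray:
    return d * np.array([-1.0, 1.0, 1.0])


# (basename, azimuth, elevation) tables.  Pairs are emitted as _r/_l with
# mirrored azimuth; midline entries have azimuth 0 and a single name.
# fmt: off
_SKIN_LAYOUT = {
    "forehead": dict(
        pairs=[("supraorbital_skin", 14, 42), ("frontal_eminence_skin", 20, 55),
               ("temporal_crest_skin", 34, 48), ("frontotemporale_skin", 42, 36)],
        mid=[("trichion_skin", 62), ("metopion_skin", 48)]),
    "brow": dict(
        pairs=[("brow_medial_skin", 8, 30), ("brow_mid_skin", 18, 31),
               ("brow_lateral_skin", 30, 29), ("brow_tail_skin", 38, 26)],
        mid=[]),
    "ocular": dict(
        pairs=[("endocanthion_skin", 9, 16), ("exocanthion_skin", 29, 17),
               ("palpebrale_sup_skin", 18, 22), ("palpebrale_inf_skin", 18, 11),
               ("orbitale_skin", 20, 4), ("infraorbital_skin", 16, -2)],
        mid=[]),
    "nasal": dict(
        pairs=[("alare_skin", 10, -16), ("alar_base_skin", 8, -21)],
        mid=[("nasion_skin", 14), ("rhinion_skin", -2), ("pronasale_skin", -12),
             ("subnasale_skin", -22)]),
    "maxillary": dict(
        pairs=[("maxillofrontale_skin", 12, 6), ("canine_fossa_skin", 14, -26),
               ("cheilion_skin", 17, -34), ("crista_philtri_skin", 5, -30),
               ("nasolabial_skin", 12, -22), ("maxillary_lateral_skin", 24, -20)],
        mid=[("labiale_superius_skin", -31), ("philtrum_skin", -27)]),
    "zygomatic": dict(
        pairs=[("zygion_skin", 46, 6), ("malar_skin", 34, -4),
               ("zygomaxillare_skin", 28, -12), ("zygo_arch_skin", 58, 8),
               ("zygofrontal_skin", 38, 20)],
        mid=[]),
    "mandibular": dict(
        pairs=[("gonion_skin", 55, -34), ("mandible_body_skin", 35, -42),
               ("mental_foramen_skin", 16, -44), ("ramus_skin", 66, -18),
               ("condylion_skin", 74, -4)],
        mid=[("labiale_inferius_skin", -40), ("pogonion_skin", -50)]),
    "calvarium_skull_base": dict(
        pairs=[("euryon_skin", 90, 30)],
        mid=[("vertex_skin", 88), ("opisthocranion_skin", 180)]),
}

_BONE_LAYOUT = {
    "forehead": dict(
        pairs=[("supraorbital_bone", 14, 40), ("frontal_eminence_bone", 21, 54),
               ("temporal_crest_bone", 34, 46), ("frontotemporale_bone", 43, 35)],
        mid=[("metopion_bone", 50), ("supraglabellare_bone", 36)]),
    "brow": dict(
        pairs=[("superciliare_bone", 10, 29), ("brow_mid_bone", 19, 30),
               ("brow_lateral_bone", 31, 28), ("brow_tail_bone", 39, 25)],
        mid=[]),
    "ocular": dict(
        pairs=[("dacryon_bone", 9, 15), ("frontomalare_orb_bone", 28, 18),
               ("orbit_sup_bone", 18, 23), ("orbit_inf_bone", 18, 9),
               ("orbitale_bone", 20, 3), ("infraorbital_for_bone", 16, -3)],
        mid=[]),
    "nasal": dict(
        pairs=[("nasomaxillare_bone", 8, 2)],
        mid=[("nasion_bone", 13), ("rhinion_bone", 0), ("nasospinale_bone", -20),
             ("acanthion_bone", -23)]),
    "maxillary": dict(
        pairs=[("canine_eminence_bone", 13, -27), ("maxillary_tuber_bone", 26, -24),
               ("zygomaxillare_inf_bone", 26, -15), ("alveolare_lat_bone", 15, -33),
               ("maxillofrontale_bone", 11, 7), ("infrazygomatic_bone", 31, -9),
               ("palatine_bone", 9, -35)],
        mid=[("prosthion_bone", -34), ("subspinale_bone", -28)]),
    "zygomatic": dict(
        pairs=[("zygion_bone", 47, 5), ("malar_bone", 35, -5),
               ("jugale_bone", 40, 1), ("zygo_arch_bone", 59, 7),
               ("frontomalare_temp_bone", 40, 19)],
        mid=[]),
    "mandibular": dict(
        pairs=[("gonion_bone", 56, -35), ("mandible_body_bone", 36, -43),
               ("mental_foramen_bone", 17, -45), ("ramus_bone", 67, -19),
               ("condylion_bone", 75, -5)],
        mid=[("infradentale_bone", -42), ("gnathion_bone", -52)]),
    "calvarium_skull_base": dict(
        pairs=[("stephanion_bone", 55, 52)],
        mid=[("bregma_bone", 80), ("lambda_bone", 155)]),
}
# fmt: on

#: the 36 bone landmarks carrying the craniometric role (breadths, heights
#: and depths describing craniofacial proportion)
CRANIOMETRIC_NAMES = tuple(
    [f"{b}_{s}" for b in (
        "supraorbital_bone", "frontal_eminence_bone", "frontotemporale_bone",  # forehead 6
        "superciliare_bone", "brow_lateral_bone",  # brow 4
        "dacryon_bone", "frontomalare_orb_bone", "orbit_sup_bone",
        "orbit_inf_bone", "orbitale_bone", "infraorbital_for_bone",  # ocular 12
        "canine_eminence_bone", "maxillary_tuber_bone", "maxillofrontale_bone",  # maxilla 6
        "zygion_bone", "jugale_bone", "frontomalare_temp_bone",  # zygoma 6
    ) for s in ("r", "l")]
    + ["nasion_bone", "nasospinale_bone"]  # nasal midline 2
)

#: the 7 static calvarial constraint landmarks (name, azimuth, elevation)
_CALVARIAL = [
    ("calv_vertex", 0.0, 90.0),
    ("calv_parietal_r", 90.0, 55.0),
    ("calv_parietal_l", -90.0, 55.0),
    ("calv_temporal_r", 95.0, 15.0),
    ("calv_temporal_l", -95.0, 15.0),
    ("calv_occiput", 180.0, 20.0),
    ("calv_opisthocranion", 180.0, -5.0),
]


def _build_dictionary() -> list[LandmarkSpec]:
    specs: list[LandmarkSpec] = []
    cranio = set(CRANIOMETRIC_NAMES)

    def emit(layout, surface, default_role):
        for region, entries in layout.items():
            for base, az, el in entries["pairs"]:
                d = _dir(az, el)
                for suffix, vec in (("r", d), ("l", _mirror(d))):
                    name = f"{base}_{suffix}"
                    role = "craniometric" if name in cranio else default_role
                    specs.append(LandmarkSpec(name, role, region, surface, tuple(vec)))
            for base, el in entries["mid"]:
                d = _dir(0.0, el) if el <= 90 else _dir(180.0, 180.0 - el)
                role = "craniometric" if base in cranio else default_role
                specs.append(LandmarkSpec(base, role, region, surface, tuple(d)))

    emit(_SKIN_LAYOUT, "skin", "skin")
    emit(_BONE_LAYOUT, "bone", "bone_moving")
    for name, az, el in _CALVARIAL:
        specs.append(
            LandmarkSpec(name, "bone_static", "calvarium_skull_base", "bone", tuple(_dir(az, el)))
        )
    for name in REFERENCE_NAMES:
        specs.append(
            LandmarkSpec(
                name,
                "reference",
                "calvarium_skull_base",
                "interior",
                _REFERENCE_CANONICAL[name],
            )
        )
    return specs


DEFAULT_DICTIONARY: tuple[LandmarkSpec, ...] = tuple(_build_dictionary())

_BY_NAME = {s.name: s for s in DEFAULT_DICTIONARY}
if len(_BY_NAME) != len(DEFAULT_DICTIONARY):  # pragma: no cover - schema sanity
    raise RuntimeError("duplicate names in the default landmark dictionary")


def spec_for(name: str) -> LandmarkSpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise InputError(f"landmark {name!r} is not in the default dictionary") from None


def names_with_role(role: str) -> list[str]:
    return [s.name for s in DEFAULT_DICTIONARY if s.role == role]


def default_names() -> list[str]:
    return [s.name for s in DEFAULT_DICTIONARY]


def counts() -> dict:
    """Landmark counts by role (skin, bone, craniometric, static, reference)."""
    return {
        "skin": len(names_with_role("skin")),
        "bone_facial": len(names_with_role("bone_moving")) + len(names_with_role("craniometric")),
        "craniometric": len(names_with_role("craniometric")),
        "bone_static": len(names_with_role("bone_static")),
        "reference": len(names_with_role("reference")),
    }
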