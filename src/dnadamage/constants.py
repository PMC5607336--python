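"""Default physical parameters of the simulation chain.

Everything here is a configuration default: geometry tables for the five
chromatin voxels and the chromosome territory allocation, the DNA-constituent
radii used both for geometry and as static reaction targets, the reaction-rate
tables of the radical chemistry stage, proton LET values, and the constants of
the DSB/Gy/Gbp normalization.

Values marked "external default" (diffusion coefficients, water dissociation
channels) are standard Geant4-DNA literature values shipped as editable
defaults; they are model inputs, not outputs of this package.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Physical constants
# ---------------------------------------------------------------------------

AVOGADRO = 6.02214076e23  # 1/mol
JOULE_PER_EV = 1.602176634e-19
JOULE_PER_KEV = 1.602176634e-16
WATER_DENSITY_KG_M3 = 1000.0

# ---------------------------------------------------------------------------
# Chromatin voxel geometry (five fibre-piece kinds tiling a 50 nm cubic grid)
# ---------------------------------------------------------------------------

VOXEL_KINDS = ("straight", "up", "down", "right", "left")

#: Per-kind voxel characteristics: nucleosome count, nucleotide-pair count and
#: fibre-solenoid parameters. The straight kind carries a full 50 nm fibre
#: segment; the four turn kinds carry a quarter-circle fibre axis (arc length
#: ~39 nm) joining orthogonal cube faces.
VOXEL_TABLE = {
    #        n_nucleosomes  n_bp  pitch_nm  fibre_length_nm
    "straight": dict(n_nucleosomes=23, n_bp=4860, pitch_nm=10.0, fibre_length_nm=50.0),
    "up":       dict(n_nucleosomes=11, n_bp=2466, pitch_nm=17.0, fibre_length_nm=39.0),
    "down":     dict(n_nucleosomes=11, n_bp=2470, pitch_nm=17.0, fibre_length_nm=39.0),
    "right":    dict(n_nucleosomes=11, n_bp=2459, pitch_nm=17.0, fibre_length_nm=39.0),
    "left":     dict(n_nucleosomes=11, n_bp=2461, pitch_nm=17.0, fibre_length_nm=39.0),
}

VOXEL_COMMON = dict(
    helix_diameter_nm=10.46,
    nucleosomes_per_turn=6,
    delta_angle_deg=60.0,
    fibre_radius_nm=17.0,
    edge_nm=50.0,
)

# ---------------------------------------------------------------------------
# DNA constituent radii (nm) and the histone complex sphere
# ---------------------------------------------------------------------------

CONSTITUENT_RADII_NM = {
    "deoxyribose": 0.29,
    "phosphate": 0.27,
    "adenine": 0.30,
    "thymine": 0.30,
    "guanine": 0.30,
    "cytosine": 0.30,
}
HISTONE_RADIUS_NM = 2.4
HYDRATION_SHELL_RADIUS_NM = 1.25  # wraps one nucleotide pair

BASES = ("adenine", "cytosine", "guanine", "thymine")
BASE_COMPLEMENT = {
    "adenine": "thymine",
    "thymine": "adenine",
    "guanine": "cytosine",
    "cytosine": "guanine",
}

# ---------------------------------------------------------------------------
# Chromosome territory allocation: domain count per chromosome copy.
# Diploid male genome: 22 autosome pairs (copies listed separately) + X + Y.
# ---------------------------------------------------------------------------

_AUTOSOME_DOMAINS = [250, 242, 198, 190, 182, 171, 159, 145, 138, 134, 135,
                     133, 114, 107, 102, 90, 83, 80, 59, 64, 47, 51]


def default_territory_table() -> list[tuple[str, int]]:
    """(chromosome copy label, number of 500 nm domains) for the 46 copies."""
    table: list[tuple[str, int]] = []
    for i, n in enumerate(_AUTOSOME_DOMAINS, start=1):
        table.append((f"{2 * i - 1}", n))
        table.append((f"{2 * i}", n))
    table.append(("X", 156))
    table.append(("Y", 57))
    return table


NUCLEUS_HALF_AXES_UM = (9.85, 7.1, 2.5)
DOMAIN_RADIUS_NM = 500.0

# ---------------------------------------------------------------------------
# Proton LET table: primary energy (MeV) -> LET_d,inf (keV/um)
# ---------------------------------------------------------------------------

LET_TABLE_KEV_PER_UM = {
    0.5: 47.9, 0.7: 36.5, 0.8: 32.6, 1.0: 27.2, 1.5: 19.9, 2.0: 16.1,
    3.0: 11.8, 4.0: 9.6, 5.0: 8.0, 10.0: 4.6, 20.0: 2.6,
}

# ---------------------------------------------------------------------------
# Chemistry: reaction-rate tables
# ---------------------------------------------------------------------------

#: OH-radical attack on DNA constituents, rates in 1e9 / (M s).
DNA_OH_RATES_1E9 = {
    "deoxyribose": 2.5,
    "adenine": 6.10,
    "guanine": 9.20,
    "thymine": 6.40,
    "cytosine": 6.10,
}

#: Default water-radical reactions, rates in 1e10 / (M s).
#: Products restricted to tracked species (H2O dropped).
WATER_REACTIONS_1E10 = [
    ("H", "e_aq", 2.65, ("OH-", "H2")),
    ("H", "OH", 1.44, ()),
    ("H", "H", 1.20, ("H2",)),
    ("H2", "OH", 4.17e-3, ("H",)),
    ("H2O2", "e_aq", 1.41, ("OH-", "OH")),
    ("H3O+", "e_aq", 2.11, ("H",)),
    ("H3O+", "OH-", 14.3, ()),
    ("OH", "e_aq", 2.95, ("OH-",)),
    ("OH", "OH", 0.44, ("H2O2",)),
    ("e_aq", "e_aq", 0.50, ("OH-", "OH-", "H2")),
]

#: Diffusion coefficients of the mobile species, m^2/s. External default
#: (Geant4-DNA chemistry module literature values); editable via config.
DIFFUSION_M2_S = {
    "e_aq": 4.9e-9,
    "OH": 2.8e-9,
    "H": 7.0e-9,
    "H2": 4.8e-9,
    "H3O+": 9.0e-9,
    "OH-": 5.0e-9,
    "H2O2": 2.3e-9,
}

#: Water dissociation channels: seed kind -> [(branching ratio, products)].
#: External default (Geant4-DNA chemistry module literature values).
DISSOCIATION_CHANNELS = {
    "ionised_water": [(1.0, ("OH", "H3O+"))],
    "excited_water": [(0.50, ("OH", "H")),
                      (0.15, ("H2", "OH", "OH")),
                      (0.35, ())],
    "solvated_electron": [(1.0, ("e_aq",))],
}

DISSOCIATION_RADIUS_NM = 1.0
CHEMISTRY_T_END_NS = 2.5
INDIRECT_SB_PROBABILITY = 2.0 / 5.0

# ---------------------------------------------------------------------------
# Damage criteria and scoring defaults
# ---------------------------------------------------------------------------

DIRECT_THRESHOLD_EV = 17.5
DIRECT_THRESHOLD_VARIANTS_EV = (12.5, 30.0)
DIRECT_LINEAR_LO_EV = 5.0
DIRECT_LINEAR_HI_EV = 37.5

CLUSTER_DISTANCE_BP = 10
MIN_FRAGMENT_BP = 10000
REL_UNCERTAINTY_STOP = 0.02
BATCH_SIZE = 1000

# ---------------------------------------------------------------------------
# Irradiation source and yield normalization (Eq-style parameter block)
# ---------------------------------------------------------------------------

SOURCE_SQUARE_UM = (16.0, 12.0)

E_1GY_KEV = 4570.0       # energy for 1 Gy in the nucleus (printed value)
MEAN_CHORD_UM = 3.5      # mean track path in the nucleus (printed value)
GENOME_GBP = 6.4         # diploid human genome size
COVERAGE_FACTOR = 0.95   # source covers 92% of the volume / 97% of the DNA
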