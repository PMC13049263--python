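"""Physical constants and protocol defaults for deuterium metabolic imaging.

All internal concentrations are mol/L; presentation layers convert to mmol/L.
Transmit fields are carried in microtesla per volt internally; the common
reporting unit μT/√W assumes a 50 Ω system (multiply by √50).
"""

#: Gyromagnetic ratio of deuterium (²H), Hz per tesla.
GAMMA_2H_HZ_PER_T = 6.536e6

#: Hydrogen-site molarity of pure water (2 sites × 55.5 mol/L H2O).
WATER_H_SITE_MOLARITY = 111.0

#: Molar mass of deuterium oxide, g/mol.
D2O_MOLAR_MASS_G_PER_MOL = 20.028

#: Deuterons per D2O molecule.
D2O_DEUTERONS_PER_MOLECULE = 2

#: System impedance assumed when converting μT/V to μT/√W.
SYSTEM_IMPEDANCE_OHM = 50.0

#: Deuterium resonance offsets relative to the HDO carrier, in ppm.
#: (HDO 4.7, Glc 3.8, Glx 2.35, Lac 1.3 ppm on the ¹H-referenced scale.)
CHEMICAL_SHIFT_PPM = {"HDO": 4.7, "Glc": 3.8, "Glx": 2.35, "Lac": 1.3}

#: Hz per ppm for ²H at 7 T.
HZ_PER_PPM_7T = 45.7

#: Literature longitudinal relaxation times used for in vivo saturation
#: correction, seconds.
T1_LITERATURE_S = {"Lac": 0.297, "Glc": 0.066, "Glx": 0.149, "HDO": 0.450}

#: Reference-phantom HDO deuteron concentration, mol/L (51 g D2O in 4.5 L).
REFERENCE_PHANTOM_CONC_MOL_L = 1.14

#: Reference-phantom T1 used in the variable-flip-angle transmit fit, seconds.
REFERENCE_PHANTOM_T1_S = 0.355

#: Quality-control thresholds for the concentration masks.
MASK_HDO_MIN_MOL_L = 0.005            # 5 mmol/L
MASK_HDO_CRLB_MAX_PERCENT = 30.0
MASK_RATIO_CRLB_MAX_PERCENT = 30.0

#: Kinetic-fit time window after glucose ingestion, minutes.
RATE_WINDOW_MIN = (20.0, 90.0)


def frequency_offsets_hz(carrier_ppm: float = 4.7,
                         hz_per_ppm: float = HZ_PER_PPM_7T) -> dict:
    """Resonance offsets in Hz from a carrier placed at ``carrier_ppm``."""
    return {m: (ppm - carrier_ppm) * hz_per_ppm
            for m, ppm in CHEMICAL_SHIFT_PPM.items()}


def ut_per_volt_to_ut_per_sqrt_watt(b1_ut_per_v: float) -> float:
    """Convert a transmit efficiency from μT/V to μT/√W (50 Ω assumption)."""
    return b1_ut_per_v * SYSTEM_IMPEDANCE_OHM ** 0.5
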