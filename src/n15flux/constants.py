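"""Physical constants and method defaults shared across the package.

Concentrations are mol fractions throughout the library (1 ppm = 1e-6);
the CLI converts to/from ppm only at the display boundary.
"""

# Gas constant, J mol-1 K-1
R_GAS = 8.314

# Natural isotope abundances (atom fractions)
NAT_15N = 0.0036630
NAT_17O = 0.000379
NAT_18O = 0.0020052

# Mol fraction of N2 in dry air
N2_AIR_FRACTION = 0.78084

# Grams of N per mole of a di-nitrogen gas (N2 or N2O): two N atoms
GRAMS_N_PER_MOL = 28.014

# Chamber and run defaults: 0.50 m x 0.50 m x 0.15 m headspace static
# chambers; the 0.10 m base insertion sits below grade and is excluded
# from the headspace volume.
CHAMBER_AREA_M2 = 0.25
CHAMBER_HEIGHT_M = 0.15

DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_PRESSURE_PA = 101325.0

# Sampling schedule: four samples spread evenly over the 201.67 min
# sampling window of a 221.83 min total closure.
SAMPLE_TIMES_MIN = (0.0, 67.22, 134.45, 201.67)
SAMPLING_WINDOW_MIN = 201.67
CLOSURE_MINUTES = 221.83

# Quality-control defaults
R2_THRESHOLD = 0.80
CONFIDENCE_LEVEL = 0.95

# Instrument precision (between-batch SDs of reference analyses):
# ratio SDs are dimensionless, the N2O concentration SD is a mol fraction.
NOISE_SD = {
    "R29": 2.85e-7,
    "R30": 8.55e-7,
    "R45": 3.79e-4,
    "R46": 9.08e-5,
    "C_N2O": 0.013e-6,
}

# Typical ambient N2O mol fraction (~332 ppb troposphere)
AMBIENT_N2O = 0.332e-6

# Reference gas N2O standard concentration (mol fraction)
N2O_STANDARD = 1.0e-6

# Unit helpers
PPM = 1e-6
M2_PER_HA = 1.0e4
MIN_PER_DAY = 1440.0
G_PER_KG = 1000.0
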