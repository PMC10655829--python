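"""Published measurement constants used as inputs to worked examples.

These are instrument readings and summary values reported for *Aquarius
paludum paludum* (three individuals per measurement route).  They are inputs
to the arithmetic pipeline — e.g. the 70% apportionment of the printed
propellant force, or the per-unit-length normalisation — never outputs the
package claims to re-measure.
"""

# individual body masses, mg (direct-route samples 1-3, indirect-route 4-6)
INSECT_WEIGHTS_MG = (39.4, 31.7, 38.9, 31.3, 37.3, 36.5)

# direct measurement (force transducer + hook probe), means
F_MLBAP_UN = 2172.0      # hook-point rowing force, μN
F_MLDIR_UN = 955.0       # tip rowing force, μN
T_MAXF_DIR_MS = 160.0    # maximum-force arrival time, ms
OMEGA_ML_DIR = 0.73      # leg angular velocity, deg/ms

# indirect measurement (high-speed video), means
A_PROP_IMG_MS2 = 40.3    # peak propellant acceleration, m/s^2
F_PROP_IMG_UN = 1408.0   # whole-body propellant force, μN
F_MLINDIR_UN = 493.0     # middle-leg rowing force, μN
T_MAXF_INDIR_MS = 21.0   # maximum-force arrival time, ms
OMEGA_ML_INDIR = 1.95    # leg angular velocity, deg/ms
V_MAX_INDIR_MM_S = 864.0  # maximum body speed, mm/s

# shared constants
CONTACT_LENGTH_MM = 11.0  # leg-water contact length, mm
APPORTIONMENT = 0.7       # middle-leg share of propellant force
N_MIDDLE_LEGS = 2
VERTICAL_FACTOR = 1.2     # resultant / horizontal force ratio
MEAN_MASS_MG = 35.9       # mean insect mass, mg
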