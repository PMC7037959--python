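# Default run configuration and model constants.
# Values here are the package-wide defaults; a user config file overrides
# any subset of them.

[run]
event = "A_20110912"        # reference summer event
scenario = "base"           # base | 2XSO3 | T310K | NUHET | HSULF
duration_s = 900.0          # 15 min of plume travel
dt_s = 0.1                  # aerosol-dynamics time step
output_interval_s = 1.0
seed = 0

[grid]
n_sections = 120            # fixed log-spaced sections
d_min_nm = 1.0
d_max_nm = 10000.0

[dilution]
alpha = 0.1                 # turbulence proportionality constant
stage1_duration_s = 1.0     # end of the jet-expansion stage
h_p0_m = 5.5                # plume height after stage 1
b_default = 1.26            # power-law exponent (fitted mean)
# vertical-dispersion scale a' by stability (m per km^b)
sigma_z_unstable = 110.62
sigma_z_neutral = 86.49
sigma_z_stable = 61.14
# stability exponent mapping (fits span 0.99-1.47; higher when unstable)
b_unstable = 1.40
b_neutral = 1.26
b_stable = 1.00

[stack]
# ROPAX ferry preset
cross_section_m2 = 0.55
exhaust_velocity_ms = 25.0
exhaust_temperature_k = 580.0

[chemistry]
so3_hydration_rate = 5.0    # s^-1, pseudo-first-order SO3 + H2O
oh_daytime = 3.0e6          # molecules cm^-3
oh_nighttime = 1.0e4
# stability mapping for events: U >= 4 m/s daytime -> unstable;
# 2-4 m/s -> neutral; U < 2 m/s or winter early morning -> stable.

[exposure]
f_inf = 0.56                # UFP infiltration factor, home microenvironment
time_at_home = 0.6          # flat diurnal home-time fraction
plume_minutes = 5.0         # plume presence per ship passage
ring_width_m = 40.0
max_radius_m = 3600.0
sector_half_width_deg = 15.0
risk_percent = 4.0          # excess mortality risk ...
risk_increment = 6250.0     # ... per this UFP increment (cm^-3)

[background]
preset = "helsinki"
total_pn = 5400.0           # cm^-3, urban UFP background
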