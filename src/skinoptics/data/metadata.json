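{
  "tissue_optical_properties.csv": {
    "description": "Absorption and reduced scattering coefficients (mean, 1 SD) of Asian epidermis, dermis and subcutaneous fat at nine clinical laser wavelengths, measured ex vivo on bloodless glass-mounted slabs by double-integrating-sphere spectroscopy with inverse Monte Carlo fitting.",
    "units": {"wavelength_nm": "nm", "mu_a_mean": "mm^-1", "mu_a_sd": "mm^-1", "mu_s_prime_mean": "mm^-1", "mu_s_prime_sd": "mm^-1"},
    "sha256": "3a16bc9415dee2ac5bc1eb41db7f8e159590f5a56df422fa087347bfd5168b0a"
  },
  "whole_blood_optical_properties.csv": {
    "description": "Absorption and reduced scattering coefficients of human whole blood at the same nine wavelengths; oxygen saturation 96%.",
    "units": {"wavelength_nm": "nm", "mu_a": "mm^-1", "mu_s_prime": "mm^-1"},
    "oxygen_saturation": 0.96,
    "sha256": "b8b49c9003cb9db6dfad8195818b560c5f9f8236089a6246084609ae9b2dc4bf"
  },
  "vessel_parameters.csv": {
    "description": "Dermal vasculature of the layered skin model: capillary plexus plus upper and deep dermal vessel plexuses (center depth, in-band blood volume fraction, vessel diameter). The capillary plexus band is 150 um thick.",
    "units": {"center_depth_um": "um", "volume_fraction_pct": "%", "diameter_um": "um"},
    "capillary_band_thickness_um": 150,
    "sha256": "c25eb72671eb41eb581afb0b775155b61ea8b2f5ab046964728fcd639a5eb012"
  }
}
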