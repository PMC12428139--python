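# Preset initial-velocity experiment designs (all concentrations in mM).
#
# Keys follow the figure-panel numbering of the assays they reproduce.  Level
# lists transcribed as ranges in the legends (fig2/fig3 saturation curves) are
# filled with 8 geometrically spaced levels spanning the stated range; grids
# printed level-by-level (fig4, fig5a, fig5b) are transcribed verbatim.
#
# Two panels carry presumed misprints and ship in both readings:
#   * fig4 MgADP series prints "0.40" inside an otherwise increasing
#     0.0125...0.071 series; `fig4_bisubstrate` reads it as 0.040 (the matching
#     fig5b series prints 0.0396), `fig4_bisubstrate_as_printed` keeps 0.40.
#   * fig2 PEP series prints "0.57 to 1.6"; a Km of 0.066 mM is not
#     identifiable from levels that all sit 9-24x above it, so `fig2_mg_pep`
#     reads the lower end as 0.057 and `fig2_mg_pep_as_printed` keeps 0.57.
#
# The fig5c/fig5d AMP series and the truncated-enzyme grids are not printed;
# those levels are package choices bracketing the relevant constants
# (Ki(AMP) = 3.3 mM; K0.5 = 3.15 and 0.17 mM).

fig2_mg_pep:
  kind: single_substrate
  a_levels: [0.057, 0.091784, 0.14779, 0.23799, 0.38322, 0.61707, 0.99364, 1.6]
  note: PEP(3-) saturation, Mg2+; fixed 0.24 mM MgADP, 1.41 mM free Mg2+

fig2_mg_pep_as_printed:
  kind: single_substrate
  a_levels: [0.57, 0.66056, 0.7655, 0.88711, 1.0281, 1.1914, 1.3807, 1.6]
  note: PEP saturation with the printed lower bound 0.57 mM

fig2_mg_adp:
  kind: single_substrate
  a_levels: [0.012, 0.017373, 0.025153, 0.036416, 0.052723, 0.076332, 0.11051, 0.16]
  note: MgADP saturation; fixed 0.66 mM PEP, 1.41 mM free Mg2+

fig2_mg_free:
  kind: single_substrate
  a_levels: [0.05, 0.081281, 0.13213, 0.21479, 0.34917, 0.56762, 0.92273, 1.5]
  note: free Mg2+ saturation; fixed 0.24 mM MgADP, 0.66 mM PEP(3-)

fig3_mn_pep:
  kind: single_substrate
  a_levels: [0.01, 0.014724, 0.021678, 0.031918, 0.046995, 0.069193, 0.10188, 0.15]
  note: PEP(3-) saturation, Mn2+; fixed 0.1 mM MnADP, 0.85 mM free Mn2+

fig3_mn_adp:
  kind: single_substrate
  a_levels: [0.01, 0.016256, 0.026426, 0.042959, 0.069834, 0.11352, 0.18455, 0.3]
  note: MnADP saturation; fixed 0.34 mM PEP(3-), 0.85 mM free Mn2+

fig3_mn_free:
  kind: single_substrate
  a_levels: [0.05, 0.071308, 0.1017, 0.14504, 0.20684, 0.29499, 0.42071, 0.6]
  note: free Mn2+ saturation; fixed 0.1 mM MnADP, 0.34 mM PEP(3-)

fig4_bisubstrate:
  kind: bisubstrate_grid
  a_levels: [0.024, 0.048, 0.097, 0.48]
  b_levels: [0.0125, 0.0166, 0.024, 0.040, 0.071]
  note: PEP(3-) x MgADP grid at 1.41 mM free Mg2+; 0.040 reading of the fourth B level

fig4_bisubstrate_as_printed:
  kind: bisubstrate_grid
  a_levels: [0.024, 0.048, 0.097, 0.48]
  b_levels: [0.0125, 0.0166, 0.024, 0.40, 0.071]
  note: same grid with the fourth B level as printed (0.40)

fig5a_oxalate:
  kind: inhibition_grid
  a_levels: [0.0097, 0.024, 0.048, 0.097, 0.484]
  i_levels: [0.0, 0.05, 0.1, 0.25, 0.4]
  note: oxalate vs PEP(3-); fixed 0.257 mM MgADP, 1.88 mM free Mg2+

fig5b_oxalate_adp:
  kind: inhibition_grid
  a_levels: [0.0125, 0.0166, 0.024, 0.0396, 0.0713]
  i_levels: [0.0, 0.02, 0.03, 0.04, 0.06]
  note: oxalate vs MgADP; fixed 1.127 mM total PEP, 1.88 mM free Mg2+

fig5c_amp:
  kind: inhibition_grid
  a_levels: [0.0097, 0.024, 0.048, 0.097, 0.484]
  i_levels: [0.0, 1.0, 2.5, 5.0, 10.0]
  note: AMP vs PEP(3-); AMP series chosen to bracket Ki = 3.3 mM

fig5d_amp_adp:
  kind: inhibition_grid
  a_levels: [0.0125, 0.0166, 0.024, 0.0396, 0.0713]
  i_levels: [0.0, 1.0, 2.5, 5.0, 10.0]
  note: AMP vs MgADP; AMP series chosen to bracket Ki = 3.3 mM

truncated_pep:
  kind: single_substrate
  a_levels: [0.5, 0.78731, 1.2397, 1.952, 3.0737, 4.8399, 7.6209, 12.0]
  note: PEP(3-) saturation of the C-terminally truncated enzyme (K0.5 = 3.15 mM)

truncated_adp:
  kind: single_substrate
  a_levels: [0.02, 0.034974, 0.061158, 0.10694, 0.18701, 0.32702, 0.57186, 1.0]
  note: MgADP saturation of the C-terminally truncated enzyme (K0.5 = 0.17 mM)
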