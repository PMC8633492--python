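# Reference band definitions for the cell-wall component library, version 1.
#
# Each component is a sum of Gaussian bands on the mid-IR fingerprint grid.
# Band centres/widths are plausible stand-ins for cell-wall constituents;
# they are NOT claims about true band assignments for any species.  The
# library only needs to be full rank and qualitatively band-like so that the
# decomposition machinery can be exercised and validated.
version: 1
grid:
  high_cm1: 1800
  low_cm1: 800
  step_cm1: 2
baseline_order: 2
components:
  cellulose:
    bands:
      - {center: 1030, width: 28, height: 1.00}
      - {center: 1160, width: 18, height: 0.45}
      - {center: 1315, width: 20, height: 0.30}
      - {center: 898,  width: 10, height: 0.20}
  hemicellulose_xylan:
    bands:
      - {center: 1043, width: 22, height: 0.90}
      - {center: 1245, width: 25, height: 0.40}
      - {center: 985,  width: 16, height: 0.35}
  lignin_G:
    bands:
      - {center: 1510, width: 14, height: 0.80}
      - {center: 1268, width: 16, height: 0.55}
      - {center: 1140, width: 14, height: 0.30}
  lignin_S:
    bands:
      - {center: 1594, width: 16, height: 0.80}
      - {center: 1328, width: 14, height: 0.50}
      - {center: 1122, width: 12, height: 0.35}
  pectin:
    bands:
      - {center: 1740, width: 20, height: 0.70}
      - {center: 1610, width: 25, height: 0.35}
      - {center: 1100, width: 22, height: 0.40}
  protein:
    bands:
      - {center: 1650, width: 25, height: 0.90}
      - {center: 1545, width: 22, height: 0.65}
      - {center: 1240, width: 20, height: 0.20}
  lipid:
    bands:
      - {center: 1745, width: 12, height: 0.85}
      - {center: 1465, width: 14, height: 0.40}
      - {center: 1160, width: 10, height: 0.15}
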