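"""Derive the physical voxel size from an acquisition project log.

The microscope's log records the horizontal field width (HFW) and image
resolution; HFW / width is the XY pixel, and the target milling thickness
is the Z step.  These three numbers calibrate every coordinate downstream.
"""

import stereogold as sg

LOG = """
[Scan]
HFW=1.49e-05
ResolutionX=6144
ResolutionY=4096
[Mill]
targetthickness="1.5E-08"
"""

params = sg.parse_acquisition_log(LOG)
print(f"HFW               : {params.hfw_um} um over {params.width_px} px")
print(f"XY pixel size     : {params.pixel_size_nm:.2f} nm")
print(f"Z milling step    : {params.z_step_nm:.1f} nm")
print()
print("Each voxel of this acquisition is therefore "
      f"{params.pixel_size_nm:.2f} x {params.pixel_size_nm:.2f} x "
      f"{params.z_step_nm:.0f} nm — strongly anisotropic, which is why all "
      "downstream distances are computed in physical units.")
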