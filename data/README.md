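# data/

Drop the public IntCal20 atmospheric calibration curve here as
`intcal20.14c` (available from intcal.org; not redistributed with this
repository) to enable:

* the acceptance test comparing calibrated 95.4% ranges of the two
  published radiocarbon determinations with their published cal BC spans;
* the IntCal20 entries in `scripts/acceptance.py` output.

Everything else in the package runs without it, using synthetic curves.
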