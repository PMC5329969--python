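import base64
import struct
from pathlib import Path

import numpy as np
import pytest

from kneenorm import simulate_plasma_spectrum, standardize
from kneenorm.simulate import SimSpec


@pytest.fixture(scope="session")
def default_spectrum():
    """The default plasma-like synthetic spectrum (5000 peaks, m/z 225-425)."""
    return simulate_plasma_spectrum(SimSpec(seed=1))


@pytest.fixture(scope="session")
def standardized_default(default_spectrum):
    """Standardized default spectrum plus its normalization curve."""
    return standardize(default_spectrum)


def _encode(values) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode()


def write_mzml(path: Path, scans, mode: str = "centroid") -> Path:
    """Write a minimal mzML file with the given (mz, intensity) scans.

    ``mode`` is 'centroid' or 'profile'; used to exercise the reader's
    centroided-only contract.
    """
    accession = "MS:1000127" if mode == "centroid" else "MS:1000128"
    name = f"{mode} spectrum"
    blocks = []
    for i, (mz, intensity) in enumerate(scans):
        mz_b64, int_b64 = _encode(list(mz)), _encode(list(intensity))
        blocks.append(f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    document = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="run1">
    <spectrumList count="{len(scans)}">{''.join(blocks)}
    </spectrumList>
  </run>
</mzML>
"""
    path.write_text(document)
    return path
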