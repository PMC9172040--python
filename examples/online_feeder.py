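"""Online mode on one machine: feeder events drive a remote server.

Starts a publisher and a remote reduction server on localhost, announces
freshly written frames as 'new file' events, then steers the server over its
HTTP control interface (status / abort) — the same wiring a beamline
deployment uses across three hosts.
"""

import tempfile
import time
from pathlib import Path

import numpy as np

from azimint.calibration import CalibrationSpec, MaskSpec
from azimint.network import EventPublisher, RemoteServer, feeder_publish, send_command
from azimint.synthetic import DEFAULT_WAVELENGTH, default_geometry, write_frame

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"
    data.mkdir()
    rng = np.random.default_rng(0)
    spec = CalibrationSpec(
        geometry=default_geometry((64, 64)),
        masks=(MaskSpec(path_to_file="", pix_per_rad_element=1.0, q_start=0.1, q_stop=1.0),),
        wavelength=DEFAULT_WAVELENGTH,
        directory=(str(data),),
        threads=4,
    )

    pub = EventPublisher("tcp://127.0.0.1:0")  # port 0: pick a free port
    server = RemoteServer(spec, out_dir=Path(tmp) / "out", subscribe=f"tcp://127.0.0.1:{pub.port}")
    try:
        while pub.n_subscribers < 1:
            time.sleep(0.02)
        for i in range(10):
            path = data / f"frame_{i:04d}.tif"
            write_frame(rng.poisson(60, (64, 64)), path)
            feeder_publish(pub, path, interval_s=0.02)  # sent only once size-stable
        server.drain(timeout_s=30)
        print("status:", send_command(server.control_port, {"command": "status"}))
        print("abort :", send_command(server.control_port, {"command": "abort"}))
        n_chi = len(list((Path(tmp) / "out").glob("*.chi")))
        print(f".chi files written: {n_chi}")
    finally:
        server.stop()
        pub.close()
# completed=10, failed=0: every announced frame was reduced exactly once;
# after 'abort' the queue is inactive and further events would be dropped.
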