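"""Generate the synthetic tournament and write trajectories + ground truth.

Writes one CSV per match (time_s, xA_m, yA_m, xB_m, yB_m) and a
ground-truth JSON per match under results/data/.
"""

import importlib.util
import json
import sys
from pathlib import Path

from retmap import pipeline as pl

HERE = Path(__file__).parent
spec = importlib.util.spec_from_file_location("cfg", HERE / "00_config.py")
cfg_mod = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg_mod)


def main() -> None:
    outdir = HERE.parent / "results" / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    config = cfg_mod.study_config()
    matches = pl._simulate_matches(config)
    index = []
    for traj, _excl, truth in matches:
        traj.to_csv(outdir / f"{traj.match_id}.csv")
        meta = {
            "group": traj.group,
            "n_scenes": len(truth.scenes),
            "scene_sample_ranges": truth.scene_sample_ranges,
            "scenes": [
                {
                    "clean_peaks": t.clean_peaks.tolist(),
                    "families": t.families,
                    "fn_labels": t.fn_labels,
                }
                for t in truth.scenes
            ],
        }
        (outdir / f"{traj.match_id}.truth.json").write_text(
            json.dumps(pl._jsonify(meta), sort_keys=True, indent=1)
        )
        index.append({"match_id": traj.match_id, "group": traj.group,
                      "path": f"results/data/{traj.match_id}.csv"})
        print(f"  {traj.match_id}: {len(truth.scenes)} planted scenes, "
              f"{traj.time[-1]:.1f} s")
    (outdir / "index.json").write_text(json.dumps(index, indent=1))
    print(f"wrote {len(matches)} matches to {outdir}")


if __name__ == "__main__":
    sys.exit(main())
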