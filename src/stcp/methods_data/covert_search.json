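{
 "edges": [
  {
   "dst": "fetch_method",
   "group": null,
   "repeat": false,
   "src": "receive_task",
   "when": null
  },
  {
   "dst": "tune_method",
   "group": null,
   "repeat": false,
   "src": "fetch_method",
   "when": null
  },
  {
   "dst": "init_cycle",
   "group": null,
   "repeat": false,
   "src": "tune_method",
   "when": null
  },
  {
   "dst": "prime_vh",
   "group": "pre",
   "repeat": false,
   "src": "init_cycle",
   "when": null
  },
  {
   "dst": "disengage_prev",
   "group": "pre",
   "repeat": false,
   "src": "init_cycle",
   "when": null
  },
  {
   "dst": "set_competition",
   "group": "pre",
   "repeat": false,
   "src": "init_cycle",
   "when": null
  },
  {
   "dst": "await_stimulus",
   "group": null,
   "repeat": false,
   "src": "prime_vh",
   "when": null
  },
  {
   "dst": "await_stimulus",
   "group": null,
   "repeat": false,
   "src": "disengage_prev",
   "when": null
  },
  {
   "dst": "await_stimulus",
   "group": null,
   "repeat": false,
   "src": "set_competition",
   "when": null
  },
  {
   "dst": "end",
   "group": null,
   "repeat": false,
   "src": "report_positive",
   "when": null
  },
  {
   "dst": "end",
   "group": null,
   "repeat": false,
   "src": "report_negative",
   "when": null
  },
  {
   "dst": "feedforward",
   "group": null,
   "repeat": false,
   "src": "await_stimulus",
   "when": null
  },
  {
   "dst": "select_cfoa",
   "group": null,
   "repeat": false,
   "src": "feedforward",
   "when": null
  },
  {
   "dst": "localize",
   "group": null,
   "repeat": false,
   "src": "select_cfoa",
   "when": "cfoa"
  },
  {
   "dst": "report_negative",
   "group": null,
   "repeat": false,
   "src": "select_cfoa",
   "when": "none"
  },
  {
   "dst": "repass",
   "group": null,
   "repeat": false,
   "src": "localize",
   "when": null
  },
  {
   "dst": "transfer_cfoa",
   "group": null,
   "repeat": false,
   "src": "repass",
   "when": null
  },
  {
   "dst": "match_goals",
   "group": null,
   "repeat": false,
   "src": "transfer_cfoa",
   "when": null
  },
  {
   "dst": "report_positive",
   "group": null,
   "repeat": false,
   "src": "match_goals",
   "when": "match"
  },
  {
   "dst": "disengage_ior",
   "group": null,
   "repeat": false,
   "src": "match_goals",
   "when": "no_match"
  },
  {
   "dst": "next_cycle",
   "group": null,
   "repeat": false,
   "src": "disengage_ior",
   "when": null
  },
  {
   "dst": "feedforward",
   "group": null,
   "repeat": true,
   "src": "next_cycle",
   "when": "continue"
  },
  {
   "dst": "report_negative",
   "group": null,
   "repeat": false,
   "src": "next_cycle",
   "when": "exhausted"
  }
 ],
 "index_keys": [
  "covert",
  "search",
  "target"
 ],
 "name": "covert_search",
 "nodes": [
  {
   "checkpoint": null,
   "id": "receive_task",
   "kind": "transfer",
   "op": "receive_task",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "fetch_method",
   "kind": "transfer",
   "op": "fetch_method",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "tune_method",
   "kind": "process",
   "op": "tune_method",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "init_cycle",
   "kind": "process",
   "op": "init_cycle",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "prime_vh",
   "kind": "process",
   "op": "prime_vh",
   "params": {
    "gain": "$priming_gain"
   }
  },
  {
   "checkpoint": null,
   "id": "disengage_prev",
   "kind": "process",
   "op": "disengage",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "set_competition",
   "kind": "set_parameters",
   "op": "set_parameters",
   "params": {
    "suppression_factor": "$suppression_factor",
    "theta": "$theta"
   }
  },
  {
   "checkpoint": null,
   "id": "await_stimulus",
   "kind": "transfer",
   "op": "await_stimulus",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "feedforward",
   "kind": "process",
   "op": "feedforward",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "localize",
   "kind": "process",
   "op": "localize",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "repass",
   "kind": "process",
   "op": "repass",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "transfer_cfoa",
   "kind": "transfer",
   "op": "transfer_cfoa",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "disengage_ior",
   "kind": "process",
   "op": "disengage",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "next_cycle",
   "kind": "process",
   "op": "next_cycle",
   "params": {
    "max_cycles": "$max_cycles"
   }
  },
  {
   "checkpoint": "selection_valid",
   "id": "select_cfoa",
   "kind": "select",
   "op": "select_cfoa",
   "params": {}
  },
  {
   "checkpoint": "selection_valid",
   "id": "match_goals",
   "kind": "select",
   "op": "match_goals",
   "params": {
    "target_channel": "$target_channel"
   }
  },
  {
   "checkpoint": null,
   "id": "report_positive",
   "kind": "process",
   "op": "report_positive",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "report_negative",
   "kind": "process",
   "op": "report_negative",
   "params": {}
  },
  {
   "checkpoint": null,
   "id": "end",
   "kind": "transfer",
   "op": "end",
   "params": {}
  }
 ]
}
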