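{
  "chlorofret_version": "0.1.0",
  "command": "inventory",
  "component_map": null,
  "config_hash": "753f09867745",
  "format": "auto",
  "inputs": [
    "/tmp/pytest-of-root/pytest-6/test_inventory_missing_file_ex0/absent.cif"
  ]
}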