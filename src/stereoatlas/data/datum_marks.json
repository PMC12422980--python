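{
 "marks": [
  {
   "name": "NucA-center",
   "kind": "intracranial",
   "structure": "NucA",
   "position_um": [
    1280.0,
    900.0,
    1500.0
   ],
   "description": "centre of nucleus A"
  },
  {
   "name": "NucA-dorsal-pole",
   "kind": "intracranial",
   "structure": "NucA",
   "position_um": [
    1280.0,
    750.0,
    1500.0
   ],
   "description": "dorsal pole of nucleus A"
  },
  {
   "name": "NucA-ventral-pole",
   "kind": "intracranial",
   "structure": "NucA",
   "position_um": [
    1280.0,
    1050.0,
    1500.0
   ],
   "description": "ventral pole of nucleus A"
  },
  {
   "name": "NucB-center",
   "kind": "intracranial",
   "structure": "NucB",
   "position_um": [
    1550.0,
    1080.0,
    1220.0
   ],
   "description": "centre of nucleus B"
  },
  {
   "name": "NucB-anterior-pole",
   "kind": "intracranial",
   "structure": "NucB",
   "position_um": [
    1550.0,
    1080.0,
    1090.0
   ],
   "description": "anterior pole of nucleus B"
  },
  {
   "name": "NucB-posterior-pole",
   "kind": "intracranial",
   "structure": "NucB",
   "position_um": [
    1550.0,
    1080.0,
    1350.0
   ],
   "description": "posterior pole of nucleus B"
  },
  {
   "name": "NucC-center",
   "kind": "intracranial",
   "structure": "NucC",
   "position_um": [
    1520.0,
    1080.0,
    1900.0
   ],
   "description": "centre of nucleus C"
  },
  {
   "name": "NucC-anterior-pole",
   "kind": "intracranial",
   "structure": "NucC",
   "position_um": [
    1520.0,
    1080.0,
    1800.0
   ],
   "description": "anterior pole of nucleus C"
  },
  {
   "name": "TubeT-anterior-end",
   "kind": "intracranial",
   "structure": "TubeT",
   "position_um": [
    1000.0,
    1150.0,
    1200.0
   ],
   "description": "anterior endpoint of the fibre tube"
  },
  {
   "name": "TubeT-posterior-end",
   "kind": "intracranial",
   "structure": "TubeT",
   "position_um": [
    1000.0,
    1150.0,
    1800.0
   ],
   "description": "posterior endpoint of the fibre tube"
  },
  {
   "name": "TubeT-mid",
   "kind": "intracranial",
   "structure": "TubeT",
   "position_um": [
    1000.0,
    1150.0,
    1500.0
   ],
   "description": "midpoint of the fibre tube"
  },
  {
   "name": "Shield-left-edge",
   "kind": "intracranial",
   "structure": "Shield",
   "position_um": [
    1130.0,
    715.0,
    1505.0
   ],
   "description": "midpoint of the plate's medial edge"
  },
  {
   "name": "Shield-right-edge",
   "kind": "intracranial",
   "structure": "Shield",
   "position_um": [
    1440.0,
    715.0,
    1505.0
   ],
   "description": "midpoint of the plate's lateral edge"
  },
  {
   "name": "L2-dorsal-pole",
   "kind": "intracranial",
   "structure": "L2",
   "position_um": [
    1280.0,
    430.0,
    1500.0
   ],
   "description": "mid-thickness of L2 at the dorsal pole"
  },
  {
   "name": "L2-anterior-pole",
   "kind": "intracranial",
   "structure": "L2",
   "position_um": [
    1280.0,
    1000.0,
    601.6304347826087
   ],
   "description": "mid-thickness of L2 at the anterior pole"
  },
  {
   "name": "L2-posterior-pole",
   "kind": "intracranial",
   "structure": "L2",
   "position_um": [
    1280.0,
    1000.0,
    2398.369565217391
   ],
   "description": "mid-thickness of L2 at the posterior pole"
  },
  {
   "name": "Isl-1-center",
   "kind": "intracranial",
   "structure": "Isl",
   "position_um": [
    1200.0,
    1180.0,
    1000.0
   ],
   "description": "centre of the first micro-island"
  },
  {
   "name": "Mx-anchor",
   "kind": "intracranial",
   "structure": "Mx",
   "position_um": [
    1280.0,
    1350.0,
    1500.0
   ],
   "description": "deep matrix anchor point on the midline"
  },
  {
   "name": "bregma",
   "kind": "cranial",
   "structure": "skull",
   "position_um": [
    1280.0,
    80.0,
    950.0
   ],
   "description": "bregma (skull midline suture)"
  },
  {
   "name": "lambda",
   "kind": "cranial",
   "structure": "skull",
   "position_um": [
    1280.0,
    260.0,
    2450.0
   ],
   "description": "lambda (skull midline suture)"
  }
 ]
}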