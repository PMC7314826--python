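{
  "expert1_4way": {
    "rows": ["model_A", "model_B", "model_C", "model_D"],
    "columns": ["expert_A", "expert_B", "expert_C", "expert_D"],
    "cells": [[7, 0, 0, 2], [1, 6, 3, 1], [0, 3, 5, 2], [1, 1, 2, 6]]
  },
  "expert2_4way": {
    "rows": ["model_A", "model_B", "model_C", "model_D"],
    "columns": ["expert_A", "expert_B", "expert_C", "expert_D"],
    "cells": [[5, 2, 1, 1], [2, 9, 0, 0], [1, 5, 1, 3], [1, 3, 3, 3]]
  },
  "expert1_severe": {
    "rows": ["model_severe", "model_non_severe"],
    "columns": ["expert_severe", "expert_non_severe"],
    "cells": [[7, 2], [2, 29]]
  },
  "expert2_severe": {
    "rows": ["model_severe", "model_non_severe"],
    "columns": ["expert_severe", "expert_non_severe"],
    "cells": [[5, 4], [4, 27]]
  },
  "expert1_mild": {
    "rows": ["model_mild", "model_non_mild"],
    "columns": ["expert_mild", "expert_non_mild"],
    "cells": [[6, 5], [4, 25]]
  },
  "expert2_mild": {
    "rows": ["model_mild", "model_non_mild"],
    "columns": ["expert_mild", "expert_non_mild"],
    "cells": [[9, 2], [10, 19]]
  }
}
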