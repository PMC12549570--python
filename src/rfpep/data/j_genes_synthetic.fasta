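>IGHJ1*01|heavy|J
AEYFQHWGQGTLVTVSS
>IGHJ2*01|heavy|J
YWYFDLWGRGTLVTVSS
>IGHJ3*01|heavy|J
DAFDVWGQGTMVTVSS
>IGHJ4*01|heavy|J
YFDYWGQGTLVTVSS
>IGHJ5*01|heavy|J
NWFDSWGQGTLVTVSS
>IGHJ6*01|heavy|J
YYYYYGMDVWGQGTTVTVSS
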