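>tir_seed_0
PCGLPWIANILDVIKSQYCESRRSLEHPFILASEYGQEILDWLTSEALNEGHLEQKTLPVAKDRVFIAGDSQKPEHNAILERPCLTITQILGTYYSKLGGARDFHNVRSTEDAYQQYRALLGQDSRWSMYFETLSGLTFNDVLHTITDIG
>tir_seed_1
PCGLPWIANILDVIKSIYLESRRSLEHPFRLALDYGQEILDWLTSEAVNEGHSEQKTLPVAKDRVFIAGDSQKPEHNAILGRPCLTITQILGTYYSKLGGARDFHNVRSTEDQDQQYRAGLGQDSRWHMYFETLSGLTFNDVLHTIVDIG
>tir_seed_2
PCGLPWIANILDVIKSQYCESRRSLEHEFILDSEYGQEELGWLTSESLNEGHLEQKTLPQAKDRFFICGDSQKPEFNAILERPCLTITQILGTYSSKLGGARDSHNVRSSEDAYQQYRALLGQDSRPSMYFETLSGLTFNDVLMTITDIG
>tir_seed_3
PCGPPWIANIPGVIKSQYCESRTGLEHPFILASIYGQVILDWLTSEALNEGHLEQKTLPVAKDRVFIAGDQQKPLHNAILERPELTITQILTTYYSKLGGARDPHNVRSTERAYQQYRALLGQDSRWSMYFETLSLLTFNDVLHTITDIG
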